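"""Macroscale hierarchy mapping via connectivity gradients.

Pipeline: Pearson functional connectivity -> row-wise sparsification (90%
default, keeping each row's strongest positive connections) -> cosine
affinity -> diffusion-map embedding (anisotropic alpha = 0.5 normalization,
diffusion time 0, i.e. lambda/(1-lambda) scaling) -> iterative Procrustes
alignment to a template -> network averages and dispersion summaries of the
principal gradient G1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ParcelSeries",
    "GradientSet",
    "functional_connectivity",
    "sparsify",
    "cosine_affinity",
    "diffusion_map_embed",
    "compute_template",
    "procrustes_align",
    "align_gradients",
    "network_average",
    "gradient_dispersion",
]


class DisconnectedGraphError(ValueError):
    """Affinity graph splits into components; embedding undefined."""


@dataclass
class ParcelSeries:
    """Parcel x time matrix for one fMRI segment."""

    data: np.ndarray
    parcel_ids: np.ndarray | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("need a parcel x time matrix with >=2 time points")
        if self.parcel_ids is None:
            self.parcel_ids = np.arange(1, self.data.shape[0] + 1)
        self.parcel_ids = np.asarray(self.parcel_ids)


@dataclass
class GradientSet:
    """Embedding coordinates (parcel x component), ordered by eigenvalue."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    alignment: str = "unaligned"  # unaligned | aligned | template
    parcel_ids: np.ndarray | None = None
    degenerate: bool = False
    disparity: float | None = None
    dropped_parcels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("components must be ordered by descending eigenvalue")
        if self.parcel_ids is None:
            self.parcel_ids = np.arange(1, self.coordinates.shape[0] + 1)

    @property
    def g1(self) -> np.ndarray:
        return self.coordinates[:, 0]


def functional_connectivity(series: ParcelSeries) -> np.ndarray:
    """Pearson correlation matrix across parcels (unit diagonal, symmetric).

    Zero-variance parcels are reported via warning and their rows/columns set
    to zero correlation (diagonal kept at 1) so the matrix stays aligned with
    the parcel list.
    """
    X = series.data
    sd = X.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        warnings.warn(f"zero-variance parcels set to r=0: {bad.tolist()}")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return R


def sparsify(matrix: np.ndarray, sparsity: float = 0.90) -> np.ndarray:
    """Row-wise sparsification: keep each row's top (1 - sparsity) fraction of
    off-diagonal entries by value (ties at the cutoff all kept), zero the rest
    and any negatives among the kept entries; diagonal zeroed."""
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    n = A.shape[0]
    out = A.copy()
    np.fill_diagonal(out, 0.0)
    k = int(np.ceil((1.0 - sparsity) * (n - 1)))  # kept entries per row
    off = out + np.where(np.eye(n, dtype=bool), -np.inf, 0.0)
    # threshold = k-th largest off-diagonal value per row; ties at it are kept
    thresh = np.sort(off, axis=1)[:, n - k][:, None]
    out[off < thresh] = 0.0
    out[out < 0] = 0.0
    if not out.any():
        warnings.warn("sparsified matrix is identically zero (no positive entries)")
    return out


def cosine_affinity(matrix: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows, negatives clipped to 0, unit diagonal."""
    A = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(A, axis=1)
    zero_rows = np.where(norms == 0)[0]
    if zero_rows.size == A.shape[0]:
        raise ValueError("all rows are zero; affinity undefined")
    if zero_rows.size:
        warnings.warn(f"zero rows in affinity input: {zero_rows.tolist()}")
    safe = np.where(norms == 0, 1.0, norms)
    C = (A @ A.T) / np.outer(safe, safe)
    C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    C[zero_rows, :] = 0.0
    C[:, zero_rows] = 0.0
    return C


def diffusion_map_embed(
    affinity: np.ndarray,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    Anisotropic normalization W' = D^-a W D^-a, Markov normalization
    P = D'^-1 W'; coordinates are the leading nontrivial right eigenvectors of
    P (normalized against the trivial constant one) scaled by lambda^t, with
    the t = 0 convention mapping to lambda/(1-lambda).
    """
    W = np.asarray(affinity, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("affinity must be square")
    if (W < 0).any():
        raise ValueError("affinity must be nonnegative")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    n_comp_graph, labels = connected_components(W > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise DisconnectedGraphError(
            f"affinity graph has {n_comp_graph} components (sizes {sizes.tolist()})"
        )
    n = W.shape[0]
    n_components = min(n_components, n - 1)

    d = W.sum(axis=1)
    Wa = W / np.outer(d**alpha, d**alpha) if alpha else W
    da = Wa.sum(axis=1)
    # symmetric conjugate of P = Da^-1 Wa shares its eigenvalues
    inv_sqrt = 1.0 / np.sqrt(da)
    S = Wa * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of P; normalize by the trivial (constant) one
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]
    lam = evals[1 : n_components + 1]
    vecs = psi[:, 1 : n_components + 1]
    if diffusion_time == 0:
        with np.errstate(divide="ignore"):
            scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    coords = vecs * scale
    gaps = np.abs(np.diff(evals[1 : n_components + 2]))
    degenerate = bool(np.any(gaps < 1e-10 * max(abs(evals[1]), 1e-30)))
    # deterministic sign: largest-magnitude entry of each component positive
    for j in range(coords.shape[1]):
        idx = np.argmax(np.abs(coords[:, j]))
        if coords[idx, j] < 0:
            coords[:, j] *= -1
    return GradientSet(coordinates=coords, eigenvalues=lam, alignment="unaligned",
                       degenerate=degenerate)


def compute_template(
    matrices: list[np.ndarray],
    n_components: int = 10,
    sparsity: float = 0.90,
    alpha: float = 0.5,
    diffusion_time: float = 0,
) -> GradientSet:
    """Template gradients from the element-wise mean connectivity matrix."""
    if not matrices:
        raise ValueError("need at least one matrix")
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"matrices have mismatched shapes: {shapes}")
    mean = np.mean(np.stack(matrices), axis=0)
    g = diffusion_map_embed(cosine_affinity(sparsify(mean, sparsity)),
                            n_components, alpha, diffusion_time)
    g.alignment = "template"
    return g


def _orthogonal_procrustes(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Best rotation/reflection Q minimizing ||source Q - target||_F."""
    U, _, Vt = np.linalg.svd(source.T @ target)
    return U @ Vt


def procrustes_align(source: GradientSet, template: GradientSet,
                     n_iter: int = 10) -> GradientSet:
    """Align one gradient set to a template by orthogonal Procrustes.

    Columns are centered, then an orthogonal transform (no scaling) is
    re-estimated ``n_iter`` times against the evolving reference (for a single
    source the reference is the fixed template, so iterations are idempotent).
    After alignment each component is sign-flipped if needed so its
    correlation with the template component is nonnegative.
    """
    return align_gradients([source], template, n_iter=n_iter)[0]


def align_gradients(sources: list[GradientSet], template: GradientSet,
                    n_iter: int = 10) -> list[GradientSet]:
    """Iteratively align several gradient sets to a template.

    Each pass aligns every source to the current reference; the reference is
    then updated to the mean of the template and the aligned sources, as in
    the standard iterative multi-set Procrustes scheme.
    """
    ref0 = template.coordinates - template.coordinates.mean(axis=0)
    n, p = ref0.shape
    mats = []
    for s in sources:
        X = s.coordinates
        if X.shape != (n, p):
            raise ValueError("source/template dimension mismatch")
        if np.linalg.matrix_rank(X) < min(X.shape):
            warnings.warn("rank-deficient source; best-fit alignment returned")
        mats.append(X - X.mean(axis=0))
    ref = ref0
    aligned = mats
    for _ in range(max(1, n_iter)):
        aligned = [X @ _orthogonal_procrustes(X, ref) for X in mats]
        ref = np.mean([ref0] + aligned, axis=0)
    out = []
    for s, A in zip(sources, aligned):
        A = A.copy()
        for j in range(p):
            t = ref0[:, j]
            if t.std() > 0 and A[:, j].std() > 0 and np.corrcoef(A[:, j], t)[0, 1] < 0:
                A[:, j] *= -1
        disparity = float(np.linalg.norm(A - ref0))
        out.append(GradientSet(coordinates=A, eigenvalues=s.eigenvalues,
                               alignment="aligned", parcel_ids=s.parcel_ids,
                               degenerate=s.degenerate, disparity=disparity))
    return out


def network_average(g: GradientSet, networks: dict[int, str]) -> dict[str, np.ndarray]:
    """Per-network mean coordinates; parcels grouped by their network label."""
    ids = np.asarray(g.parcel_ids)
    missing = [int(i) for i in ids if int(i) not in networks]
    if missing:
        raise ValueError(f"parcels without network labels: {missing}")
    out: dict[str, np.ndarray] = {}
    for net in sorted(set(networks[int(i)] for i in ids)):
        sel = np.array([networks[int(i)] == net for i in ids])
        out[net] = g.coordinates[sel].mean(axis=0)
    return out


def gradient_dispersion(g: GradientSet, component: int = 1) -> tuple[float, float]:
    """(range, SD) of the chosen gradient component across parcels."""
    x = g.coordinates[:, component - 1]
    return float(x.max() - x.min()), float(x.std())
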