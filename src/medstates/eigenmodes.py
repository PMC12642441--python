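"""Geometric eigenmode decomposition of surface activity.

The Laplace-Beltrami operator on a triangle mesh is discretised with
cotangent stiffness weights and a lumped (diagonal) mass matrix; the
generalized eigenproblem  A psi = lambda M psi  yields a spatial-frequency
ordered, M-orthonormal basis.  Surface time series are projected onto the
basis (omega = Psi^T M y), and per-mode power |omega_k(t)| and energy
|omega_k(t)|^2 lambda_k^2 are summarized per segment on a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

__all__ = [
    "EigenmodeBasis",
    "SpectralActivation",
    "assemble_lbo",
    "solve_eigenmodes",
    "project_timeseries",
    "spectra",
    "segment_summary",
    "eigengroup_summary",
    "spherical_harmonic_groups",
]


class MeshError(ValueError):
    """Raised for degenerate or non-manifold input meshes."""


@dataclass
class EigenmodeBasis:
    """Eigenpairs (ascending lambda_k, M-orthonormal psi_k) plus mass matrix."""

    eigenvalues: np.ndarray  # (K,)
    modes: np.ndarray  # (V, K)
    mass: sp.spmatrix  # (V, V) diagonal lumped mass

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        if np.any(np.diff(self.eigenvalues) < -1e-9):
            raise ValueError("eigenvalues must be ascending")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


@dataclass
class SpectralActivation:
    """Mode coefficients omega (K x T) with derived power/energy spectra."""

    coefficients: np.ndarray
    power: np.ndarray | None = None
    energy: np.ndarray | None = None
    total_power: np.ndarray | None = None
    total_energy: np.ndarray | None = None


def assemble_lbo(vertices: np.ndarray, faces: np.ndarray):
    """Cotangent stiffness and lumped mass matrix for a triangle mesh.

    Returns (A, M): A symmetric positive semidefinite with zero row sums,
    M diagonal with trace equal to the total surface area (one third of each
    incident triangle's area per vertex).
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=int)
    if V.ndim != 2 or V.shape[1] != 3 or F.ndim != 2 or F.shape[1] != 3:
        raise MeshError("need vertices (V,3) and triangle faces (F,3)")
    if F.min() < 0 or F.max() >= len(V):
        raise MeshError("face indices out of range")
    i, j, k = F[:, 0], F[:, 1], F[:, 2]
    e_jk = V[k] - V[j]
    e_ki = V[i] - V[k]
    e_ij = V[j] - V[i]
    area2 = np.linalg.norm(np.cross(e_ij, -e_ki), axis=1)  # 2 * triangle area
    bad = np.where(area2 <= 1e-14)[0]
    if bad.size:
        raise MeshError(f"degenerate (zero-area) faces: {bad.tolist()}")
    # cot of the angle opposite each edge: cot = dot / (2*area)
    cot_i = np.einsum("ij,ij->i", -e_ij, e_ki) / area2  # angle at i, opposite jk
    cot_j = np.einsum("ij,ij->i", -e_jk, e_ij) / area2  # angle at j, opposite ki
    cot_k = np.einsum("ij,ij->i", -e_ki, e_jk) / area2  # angle at k, opposite ij

    n = len(V)
    rows = np.concatenate([j, k, k, i, i, j])
    cols = np.concatenate([k, j, i, k, j, i])
    vals = -0.5 * np.concatenate([cot_i, cot_i, cot_j, cot_j, cot_k, cot_k])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = A - sp.diags(np.asarray(A.sum(axis=1)).ravel())

    area = area2 / 2.0
    mass = np.zeros(n)
    for idx in (i, j, k):
        np.add.at(mass, idx, area / 3.0)
    M = sp.diags(mass)
    return A.tocsr(), M.tocsr()


def solve_eigenmodes(stiffness, mass, n_modes: int = 200) -> EigenmodeBasis:
    """Smallest ``n_modes`` generalized eigenpairs A psi = lambda M psi.

    Modes are M-orthonormal with a deterministic sign convention (first
    entry exceeding 1e-8 in magnitude is positive); lambda_1 ~ 0 corresponds
    to the constant mode.  A dense solver is used when n_modes approaches the
    vertex count (the sparse Lanczos solver requires n_modes < V).
    """
    A = sp.csr_matrix(stiffness)
    M = sp.csr_matrix(mass)
    n = A.shape[0]
    if n_modes > n:
        raise ValueError("cannot request more modes than vertices")
    if n_modes > n - 2 or n < 200:
        from scipy.linalg import eigh

        evals, evecs = eigh(A.toarray(), M.toarray())
        evals, evecs = evals[:n_modes], evecs[:, :n_modes]
    else:
        # shift-invert around a small negative sigma: A is singular at 0
        evals, evecs = eigsh(A, k=n_modes, M=M, sigma=-1e-6, which="LM")
    order = np.argsort(evals)
    evals, evecs = evals[order], evecs[:, order]
    evals = np.where(np.abs(evals) < 1e-10 * max(evals.max(), 1.0), 0.0, evals)
    # enforce M-orthonormality scale and sign convention
    m_diag = M.diagonal()
    norms = np.sqrt(np.einsum("vk,v,vk->k", evecs, m_diag, evecs))
    evecs = evecs / norms
    for kk in range(evecs.shape[1]):
        col = evecs[:, kk]
        idx = np.argmax(np.abs(col) > 1e-8)
        if col[idx] < 0:
            evecs[:, kk] *= -1
    return EigenmodeBasis(eigenvalues=evals, modes=evecs, mass=M)


def project_timeseries(data: np.ndarray, basis: EigenmodeBasis,
                       vertex_mask: np.ndarray | None = None,
                       method: str = "mass") -> SpectralActivation:
    """Project vertex x time data onto the eigenmode basis.

    With the full vertex set and M-orthonormal modes the mass-weighted
    least-squares solution is closed form, omega = Psi^T M y.  With a vertex
    mask (e.g. a medial wall) the normal equations are solved on the retained
    vertices (general weighted least squares).  ``method='pseudoinverse'``
    ignores the mass weighting.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != basis.modes.shape[0]:
        raise ValueError(
            f"data has {Y.shape[0]} vertices, basis has {basis.modes.shape[0]}"
        )
    if not np.isfinite(Y).all():
        raise ValueError("data must be finite")
    psi = basis.modes
    if vertex_mask is not None:
        keep = np.asarray(vertex_mask, dtype=bool)
        w = basis.mass.diagonal()[keep] if method == "mass" else None
        Psi, Yk = psi[keep], Y[keep]
        if w is not None:
            G = Psi.T * w @ Psi
            omega = np.linalg.solve(G, (Psi.T * w) @ Yk)
        else:
            omega = np.linalg.lstsq(Psi, Yk, rcond=None)[0]
    elif method == "mass":
        omega = psi.T @ (basis.mass @ Y)
    else:
        omega = np.linalg.lstsq(psi, Y, rcond=None)[0]
    return SpectralActivation(coefficients=omega)


def spectra(activation: SpectralActivation, basis: EigenmodeBasis) -> SpectralActivation:
    """Power |omega_k(t)| and energy |omega_k(t)|^2 lambda_k^2, with per-time totals."""
    omega = activation.coefficients
    power = np.abs(omega)
    energy = power**2 * (basis.eigenvalues[:, None] ** 2)
    return SpectralActivation(
        coefficients=omega,
        power=power,
        energy=energy,
        total_power=power.sum(axis=0),
        total_energy=energy.sum(axis=0),
    )


def segment_summary(spec: SpectralActivation, log_base: float = 10,
                    log_floor: float = 1e-12) -> dict[str, np.ndarray]:
    """Per-mode mean and max power/energy over the segment, log-transformed.

    Temporal averaging happens first, the log transform second (log of the
    mean, not mean of logs); values below ``log_floor`` are floored before
    the log.  Totals are the per-time sums averaged over the segment.
    """
    if spec.power is None:
        raise ValueError("call spectra() first")
    logb = np.log(log_base)

    def _log(x):
        return np.log(np.maximum(x, log_floor)) / logb

    return {
        "mean_power": _log(spec.power.mean(axis=1)),
        "max_power": _log(spec.power.max(axis=1)),
        "mean_energy": _log(spec.energy.mean(axis=1)),
        "max_energy": _log(spec.energy.max(axis=1)),
        "total_power": float(spec.total_power.mean()),
        "total_energy": float(spec.total_energy.mean()),
    }


def spherical_harmonic_groups(n_modes: int) -> list[np.ndarray]:
    """Partition mode indices 0..K-1 into blocks of sizes 1, 3, 5, 7, ...

    Mirrors the degeneracy pattern 2l+1 of Laplace-Beltrami eigenmodes on a
    sphere; the last group is truncated at K.
    """
    groups, start, l = [], 0, 0
    while start < n_modes:
        size = 2 * l + 1
        groups.append(np.arange(start, min(start + size, n_modes)))
        start += size
        l += 1
    return groups


def eigengroup_summary(per_mode: np.ndarray,
                       groups: list[np.ndarray] | None = None) -> np.ndarray:
    """Group means of a per-mode summary vector.

    ``groups`` must partition 0..K-1; defaults to spherical-harmonic blocks.
    """
    x = np.asarray(per_mode, dtype=float)
    if groups is None:
        groups = spherical_harmonic_groups(x.size)
    flat = np.concatenate(groups)
    if sorted(flat.tolist()) != list(range(x.size)):
        raise ValueError("groups must partition the mode indices exactly")
    return np.array([x[g].mean() for g in groups])
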