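"""Synthetic datasets with the statistical structure the analyses assume.

Every generator is a pure function of (spec, seed): a single integer seed
drives a hierarchical seed tree (one child stream per participant x
condition) so that subsets reproduce independently.  Each generator returns
a ``GroundTruth`` holding the planted effects so downstream recovery can be
scored.

What is emulated
----------------
* Local synchrony: voxel series are a parcel-shared signal mixed with
  i.i.d. noise; the mixing weight follows a logistic function of orthonormal
  polynomial codes across the eight ordered states, planting linear /
  quadratic / cubic trends in Kendall's W by construction (anterior negative,
  posterior positive linear trends by default).
* Hierarchy flattening: parcel series realize an exponential-decay
  correlation kernel over a latent 1-D coordinate; meditation-state matrices
  mix the hierarchy kernel with an order-scrambled copy of itself, with the
  mixing weight solved so that the noiseless embedding's principal-gradient
  range shrinks by exactly ``gradient_compression``.
* Global dynamics: vertex series are sums of eigenmodes with per-state
  amplitudes (a U-shaped schedule by default), planting log-power trends.
* Brain-behavior coupling: behavior tables are generated from a latent score
  built with planted saliences, at a chosen latent correlation, with
  missing-completely-at-random gaps.
* Term decoding: a term library with one planted map at an exact target
  correlation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import CONTROLS, STATES, Parcellation, SegmentTable, VoxelImage
from .trends import orthogonal_poly_codes

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "generate_reho_dataset",
    "generate_gradient_dataset",
    "generate_mesh",
    "generate_mode_timeseries",
    "generate_behavior_tables",
    "generate_term_library",
    "population_hierarchy_correlation",
]

#: default planted ReHo trend coefficients (logistic scale) per region group
DEFAULT_TREND_MAP: dict[str, tuple[float, float, float]] = {
    "anterior": (-1.0, 0.0, 0.0),
    "midline": (0.0, 0.75, 0.0),
    "posterior": (1.0, 0.0, 0.0),
}

#: default U-shaped eigenmode amplitude schedule across the 8 states
DEFAULT_MODE_AMPLITUDES = np.array([2.0, 1.5, 1.0, 0.8, 0.7, 0.9, 1.3, 1.8])


@dataclass
class SimulationSpec:
    """Study-scale description of a synthetic dataset.

    Defaults mirror the study conditions: 20 participants, eight ordered
    states plus two control tasks, 60 volumes per segment on a desk-scale
    10x10x10 grid with 27 block parcels.
    """

    n_participants: int = 20
    states: tuple[str, ...] = STATES
    controls: tuple[str, ...] = CONTROLS
    grid: tuple[int, int, int] = (10, 10, 10)
    parcel_grid: tuple[int, int, int] = (3, 3, 3)
    t_per_segment: int = 60
    trend_map: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TREND_MAP))
    base_weight_logit: float = 0.0
    n_parcels_gradient: int = 60
    gradient_compression: dict[str, float] = field(default_factory=dict)
    hierarchy_lengthscale: float = 0.5
    mode_amplitudes: np.ndarray = field(
        default_factory=lambda: DEFAULT_MODE_AMPLITUDES.copy())
    latent_correlation: float = 0.7
    noise_sd: float = 1.0
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 6 for g in self.grid):
            raise ValueError("grid must be at least 6x6x6")
        if self.t_per_segment < 20:
            raise ValueError("need at least 20 volumes per segment")
        for c in self.gradient_compression.values():
            if not 0 < c <= 1:
                raise ValueError("gradient_compression must be in (0, 1]")
        if not -1 <= self.latent_correlation <= 1:
            raise ValueError("latent correlation must be in [-1, 1]")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for coefs in self.trend_map.values():
            if not np.all(np.isfinite(coefs)):
                raise ValueError("trend coefficients must be finite")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.states) + tuple(self.controls)

    def seed_tree(self, label: str) -> np.random.SeedSequence:
        """Child seed stream for a named sub-generator (stable across runs)."""
        h = zlib.crc32(label.encode()) % (2**31)
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(h,))


@dataclass
class GroundTruth:
    """Planted effects recorded by a generator (acceptance oracle)."""

    parcel_trends: dict[int, tuple[float, float, float]] | None = None
    parcel_groups: dict[int, str] | None = None
    mixing_weights: np.ndarray | None = None  # parcels x states
    base_weight: float | None = None
    latent_coordinates: np.ndarray | None = None
    compression: dict[str, float] | None = None
    hierarchy_mixing: dict[str, float] | None = None
    mode_amplitudes: np.ndarray | None = None
    brain_saliences: np.ndarray | None = None
    behavior_saliences: dict[str, np.ndarray] | None = None
    latent_correlation: float | None = None
    planted_term: str | None = None
    planted_r: float | None = None


# ---------------------------------------------------------------------------
# local-synchrony (ReHo) substrate


def block_parcellation(grid, parcel_grid) -> Parcellation:
    """Split the grid into contiguous blocks; labels 1..n in raster order.

    Region groups ("anterior" / "midline" / "posterior") are thirds along the
    first spatial axis, which keeps them deterministic and
    resolution-independent.
    """
    labels = np.zeros(grid, dtype=int)
    xs = np.array_split(np.arange(grid[0]), parcel_grid[0])
    ys = np.array_split(np.arange(grid[1]), parcel_grid[1])
    zs = np.array_split(np.arange(grid[2]), parcel_grid[2])
    names, networks = {}, {}
    pid = 0
    for xi, xblk in enumerate(xs):
        group = ("anterior", "midline", "posterior")[min(xi * 3 // len(xs), 2)] \
            if parcel_grid[0] != 3 else ("anterior", "midline", "posterior")[xi]
        for yblk in ys:
            for zblk in zs:
                pid += 1
                labels[np.ix_(xblk, yblk, zblk)] = pid
                names[pid] = f"{group}_{pid}"
                networks[pid] = group
    return Parcellation(labels=labels, names=names, networks=networks)


def mixing_weights(spec: SimulationSpec) -> tuple[np.ndarray, Parcellation, dict]:
    """Per-parcel, per-state signal/noise mixing weight w in (0, 1).

    w(parcel, state) = logistic(base + l*P1 + q*P2 + c*P3) with orthonormal
    polynomial codes over the ordered states; control conditions use the base
    weight only.
    """
    parc = block_parcellation(spec.grid, spec.parcel_grid)
    n_states = len(spec.states)
    codes = orthogonal_poly_codes(n_states, 3)
    groups = {int(p): parc.networks[int(p)] for p in parc.parcel_ids}
    trends = {int(p): tuple(spec.trend_map.get(groups[int(p)], (0.0, 0.0, 0.0)))
              for p in parc.parcel_ids}
    W = np.empty((len(parc.parcel_ids), n_states))
    for i, p in enumerate(parc.parcel_ids):
        l, q, c = trends[int(p)]
        W[i] = expit(spec.base_weight_logit
                     + l * codes[:, 0] + q * codes[:, 1] + c * codes[:, 2])
    return W, parc, trends


def generate_reho_dataset(spec: SimulationSpec):
    """Volumetric dataset with planted local-synchrony state trends.

    Returns (images, parcellation, segments, truth) where ``images`` maps
    (participant, condition) to a 4D :class:`VoxelImage`.  Each voxel's
    series is sqrt(w) * parcel-shared signal + sqrt(1-w) * i.i.d. noise, so
    higher w yields higher Kendall's W by construction.
    """
    W, parc, trends = mixing_weights(spec)
    base_w = float(expit(spec.base_weight_logit))
    labels = parc.labels
    pids = parc.parcel_ids
    images: dict[tuple[str, str], VoxelImage] = {}
    seg_rows = []
    T = spec.t_per_segment
    for p in range(spec.n_participants):
        pname = f"sub{p + 1:02d}"
        for cond in spec.conditions:
            rng = np.random.default_rng(spec.seed_tree(f"reho/{pname}/{cond}"))
            if cond in spec.states:
                s_idx = spec.states.index(cond)
                w_parcel = {int(pid): W[i, s_idx] for i, pid in enumerate(pids)}
            else:
                w_parcel = {int(pid): base_w for pid in pids}
            data = np.empty(spec.grid + (T,))
            for pid in pids:
                sel = labels == pid
                shared = rng.standard_normal(T)
                noise = rng.standard_normal((int(sel.sum()), T))
                w = w_parcel[int(pid)]
                data[sel] = np.sqrt(w) * shared + np.sqrt(1.0 - w) * noise
            images[(pname, cond)] = VoxelImage(data=data)
            seg_rows.append({"participant": pname, "session": 1, "run": cond,
                             "condition": cond, "start": 0, "end": T})
    truth = GroundTruth(parcel_trends=trends,
                        parcel_groups={int(p): parc.networks[int(p)]
                                       for p in pids},
                        mixing_weights=W, base_weight=base_w)
    return images, parc, SegmentTable(pd.DataFrame(seg_rows)), truth


# ---------------------------------------------------------------------------
# hierarchy / gradient substrate


def population_hierarchy_correlation(n_parcels: int, lengthscale: float = 0.5,
                                     coordinates: np.ndarray | None = None
                                     ) -> np.ndarray:
    """Noiseless parcel correlation matrix from a latent 1-D hierarchy.

    Parcel i sits at coordinate g_i in [-1, 1]; correlation decays
    exponentially with |g_i - g_j| (Ornstein-Uhlenbeck kernel), which keeps
    the matrix positive definite for any coordinate set.
    """
    g = (np.linspace(-1.0, 1.0, n_parcels) if coordinates is None
         else np.asarray(coordinates, dtype=float))
    K = np.exp(-np.abs(g[:, None] - g[None, :]) / lengthscale)
    return K


def _flattened_correlation(K: np.ndarray, perm: np.ndarray, a: float) -> np.ndarray:
    """Mixture of the hierarchy kernel and its order-scrambled copy."""
    R = a * K + (1.0 - a) * K[np.ix_(perm, perm)]
    np.fill_diagonal(R, 1.0)
    return R


def solve_flattening_weight(K: np.ndarray, perm: np.ndarray, target_ratio: float,
                            embed: Callable[[np.ndarray], float],
                            tol: float = 0.01) -> float:
    """Mixing weight whose noiseless embedding range ratio equals the target.

    ``embed`` maps a correlation matrix to a G1 range (the analysis pipeline
    on the noiseless matrix).  Bisection on the monotone region [a_lo, 1].
    """
    if not 0 < target_ratio <= 1:
        raise ValueError("compression must be in (0, 1]")
    if target_ratio == 1.0:
        return 1.0
    base = embed(K)
    lo, hi = 0.55, 1.0  # ratio is monotone in the mixing weight on [0.55, 1]
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r = embed(_flattened_correlation(K, perm, mid)) / base
        if abs(r - target_ratio) < tol:
            return mid
        if r > target_ratio:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def generate_gradient_dataset(spec: SimulationSpec, embed=None):
    """Parcel time series per participant x condition with planted flattening.

    ``embed`` maps a correlation matrix to a G1 range; it defaults to the
    analysis pipeline (sparsify 0.90 -> cosine affinity -> diffusion map) and
    is used only to calibrate the flattening mixture on the noiseless matrix.
    Returns (series, networks, truth) where series maps (participant,
    condition) to a parcel x time array.
    """
    from .gradients import (cosine_affinity, diffusion_map_embed,
                            gradient_dispersion, sparsify)

    P = spec.n_parcels_gradient
    if P < 20:
        raise ValueError("need at least 20 parcels")
    if embed is None:
        def embed(R):
            g = diffusion_map_embed(cosine_affinity(sparsify(R.copy(), 0.90)), 10)
            return gradient_dispersion(g, 1)[0]

    K = population_hierarchy_correlation(P, spec.hierarchy_lengthscale)
    g = np.linspace(-1.0, 1.0, P)
    rng_perm = np.random.default_rng(spec.seed_tree("gradients/perm"))
    perm = rng_perm.permutation(P)

    compression = {c: spec.gradient_compression.get(c, 1.0)
                   for c in spec.conditions}
    weight_cache: dict[float, float] = {}
    mixing: dict[str, float] = {}
    chols: dict[str, np.ndarray] = {}
    for cond in spec.conditions:
        c = compression[cond]
        if c not in weight_cache:
            weight_cache[c] = solve_flattening_weight(K, perm, c, embed)
        a = weight_cache[c]
        mixing[cond] = a
        chols[cond] = np.linalg.cholesky(_flattened_correlation(K, perm, a)
                                         + 1e-10 * np.eye(P))

    series: dict[tuple[str, str], np.ndarray] = {}
    T = spec.t_per_segment
    for p in range(spec.n_participants):
        pname = f"sub{p + 1:02d}"
        for cond in spec.conditions:
            rng = np.random.default_rng(
                spec.seed_tree(f"gradients/{pname}/{cond}"))
            Z = rng.standard_normal((P, T))
            series[(pname, cond)] = chols[cond] @ Z
    networks = {i + 1: ("unimodal" if gi < 0 else "transmodal")
                for i, gi in enumerate(g)}
    truth = GroundTruth(latent_coordinates=g, compression=compression,
                        hierarchy_mixing=mixing)
    return series, networks, truth


# ---------------------------------------------------------------------------
# surface / eigenmode substrate


def generate_mesh(kind: str = "icosphere", subdivisions: int = 3):
    """Closed unit-radius triangle mesh (icosphere; 10*4^n + 2 vertices)."""
    if kind != "icosphere":
        raise ValueError(f"unknown mesh kind: {kind}")
    if not 1 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in [1, 6]")
    import trimesh

    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)


def generate_mode_timeseries(basis, schedule: np.ndarray, noise_sd: float = 0.0,
                             seed: int | None = None, t_per_segment: int = 60,
                             states: tuple[str, ...] = STATES):
    """Vertex x time data per state: y(t) = sum_k a_k(state) z_k(t) psi_k + eps.

    ``schedule`` is (n_modes x n_states) amplitudes (rows beyond the basis
    size are not allowed); z_k(t) are independent unit-variance series.
    Returns (data, truth) with data mapping state -> V x T array.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    A = np.atleast_2d(np.asarray(schedule, dtype=float))
    if A.shape[1] != len(states):
        raise ValueError("schedule must have one column per state")
    if A.shape[0] > basis.n_modes:
        raise ValueError("schedule indexes modes beyond the basis")
    root = np.random.SeedSequence(seed)
    data: dict[str, np.ndarray] = {}
    V = basis.modes.shape[0]
    for s, (state, child) in enumerate(zip(states, root.spawn(len(states)))):
        rng = np.random.default_rng(child)
        Z = rng.standard_normal((A.shape[0], t_per_segment))
        Y = basis.modes[:, : A.shape[0]] @ (A[:, s, None] * Z)
        if noise_sd > 0:
            Y = Y + noise_sd * rng.standard_normal((V, t_per_segment))
        data[state] = Y
    return data, GroundTruth(mode_amplitudes=A)


# ---------------------------------------------------------------------------
# behavior substrate


def generate_behavior_tables(spec: SimulationSpec, brain_summaries: np.ndarray,
                             row_keys: pd.DataFrame | None = None,
                             n_columns: dict[str, int] | None = None,
                             discretize: bool = True):
    """Phenomenology / traits / cognition tables coupled to brain summaries.

    behavior = (latent score from planted brain saliences) * (behavior
    saliences) * rho + noise; phenomenology is mapped to integer 1-10
    ratings (skipped when ``discretize=False`` for exact-identity checks)
    and missing entries are inserted completely at random at
    ``spec.missing_rate`` in phenomenology and traits.
    """
    X = np.asarray(brain_summaries, dtype=float)
    if X.ndim != 2:
        raise ValueError("brain_summaries must be rows x metrics")
    n = X.shape[0]
    if row_keys is not None and len(row_keys) != n:
        raise ValueError("row_keys misaligned with brain_summaries")
    n_columns = n_columns or {"phenomenology": 4, "traits": 6, "cognition": 5}
    rho = spec.latent_correlation
    rng = np.random.default_rng(spec.seed_tree("behavior"))
    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    # plant the coupling along the brain matrix's leading principal axis so
    # the latent score is exactly recoverable by a cross-covariance SVD
    U1, _, Vt1 = np.linalg.svd(Xz, full_matrices=False)
    v = Vt1[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
        U1 = -U1
    latent = U1[:, 0]
    lz = (latent - latent.mean()) / (latent.std() if latent.std() > 0 else 1.0)

    tables: dict[str, pd.DataFrame] = {}
    behavior_saliences: dict[str, np.ndarray] = {}
    for domain, q in n_columns.items():
        u = rng.standard_normal(q)
        u /= np.linalg.norm(u)
        behavior_saliences[domain] = u
        noise = rng.standard_normal((n, q))
        Y = rho * np.outer(lz, u) + np.sqrt(max(0.0, 1 - rho**2)) \
            * spec.noise_sd * noise
        if domain == "phenomenology" and discretize:
            # affine map to the 1-10 Likert range, then integer ratings
            Y = np.clip(np.rint(5.5 + 2.0 * Y), 1, 10)
        if domain in ("phenomenology", "traits") and spec.missing_rate > 0:
            gaps = rng.random((n, q)) < spec.missing_rate
            Y = np.where(gaps, np.nan, Y)
        cols = [f"{domain[:4]}_{j + 1}" for j in range(q)]
        df = pd.DataFrame(Y, columns=cols)
        if row_keys is not None:
            df = pd.concat([row_keys.reset_index(drop=True), df], axis=1)
        tables[domain] = df
    truth = GroundTruth(brain_saliences=v, behavior_saliences=behavior_saliences,
                        latent_correlation=rho)
    return tables, truth


# ---------------------------------------------------------------------------
# term-map library


def generate_term_library(n_terms: int, n_locations: int,
                          planted: tuple[str, np.ndarray, float] | None = None,
                          seed: int | None = None):
    """Library of term maps; one planted map at an exact target correlation.

    The planted map is built as r * z(target) + sqrt(1 - r^2) * e with e the
    z-scored residual of a noise draw against the target, so its sample
    correlation with the target equals ``r_target`` exactly.
    """
    from .decoding import TermMapLibrary

    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((n_terms, n_locations))
    terms = [f"term_{i + 1:03d}" for i in range(n_terms)]
    truth = GroundTruth()
    if planted is not None:
        name, target, r_target = planted
        if not 0 < r_target <= 1:
            raise ValueError("r_target must be in (0, 1]")
        t = np.asarray(target, dtype=float).ravel()
        if t.size != n_locations:
            raise ValueError("target map size mismatch")
        tz = (t - t.mean()) / t.std(ddof=0)
        e = rng.standard_normal(n_locations)
        e = e - e.mean() - tz * (e @ tz) / n_locations  # orthogonal to target
        e /= np.sqrt((e**2).mean())
        maps[0] = r_target * tz + np.sqrt(1.0 - r_target**2) * e
        terms[0] = name
        truth.planted_term = name
        truth.planted_r = float(r_target)
    return TermMapLibrary(terms=terms, maps=maps), truth
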