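"""Psychobehavioral term-map decoding and subgroup robustness checks.

Decoding correlates an unthresholded state-minus-control delta map with each
map in a term library and ranks terms; robustness checks correlate two
subgroups' state maps and test whether that spatial similarity rises across
the ordered states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TermMapLibrary",
    "DecodingResult",
    "delta_map",
    "correlation_decode",
    "subgroup_similarity",
    "similarity_trend",
]


@dataclass
class TermMapLibrary:
    """One spatial map per psychobehavioral term, on a common grid."""

    terms: list[str]
    maps: np.ndarray  # n_terms x n_locations

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] != len(self.terms):
            raise ValueError("maps must be terms x locations")
        sd = np.nanstd(self.maps, axis=1)
        if (sd == 0).any():
            bad = [self.terms[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"constant term maps not allowed: {bad}")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class DecodingResult:
    terms: list[str]
    r: np.ndarray
    ranks: np.ndarray  # 1 = highest r
    top_positive: list[str]
    top_negative: list[str]


def delta_map(state_map: np.ndarray, control_map: np.ndarray) -> np.ndarray:
    """Element-wise state minus control, unthresholded; NaNs propagate."""
    a = np.asarray(state_map, dtype=float)
    b = np.asarray(control_map, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a - b


def correlation_decode(map_values: np.ndarray, library: TermMapLibrary,
                       top_k: int = 10, min_locations: int = 10) -> DecodingResult:
    """Correlate a map with every term map and rank terms by r (descending).

    Correlations use jointly non-missing locations per term; the input map
    must be non-constant over those locations.
    """
    x = np.asarray(map_values, dtype=float).ravel()
    if x.size != library.maps.shape[1]:
        raise ValueError("map is not on the library grid")
    rs = np.empty(len(library))
    for i, tm in enumerate(library.maps):
        ok = np.isfinite(x) & np.isfinite(tm)
        if ok.sum() < min_locations:
            raise ValueError(f"<{min_locations} joint locations for term "
                             f"{library.terms[i]!r}")
        if x[ok].std() == 0:
            raise ValueError("constant input map; correlations undefined")
        rs[i] = stats.pearsonr(x[ok], tm[ok])[0]
    order = np.argsort(-rs, kind="stable")
    ranks = np.empty(len(library), dtype=int)
    ranks[order] = np.arange(1, len(library) + 1)
    top_pos = [library.terms[i] for i in order[:top_k]]
    top_neg = [library.terms[i] for i in order[::-1][:top_k]]
    return DecodingResult(terms=list(library.terms), r=rs, ranks=ranks,
                          top_positive=top_pos, top_negative=top_neg)


def subgroup_similarity(maps_a: dict[str, np.ndarray],
                        maps_b: dict[str, np.ndarray],
                        n_perm: int = 10000,
                        seed: int | None = None) -> dict[str, dict]:
    """Per-state spatial correlation between two subgroups with permutation p.

    The null permutes one map's locations; p = (1 + #{|r_perm| >= |r_obs|}) /
    (n_perm + 1).  Location shuffling assumes exchangeability, which spatial
    autocorrelation in real maps violates; on synthetic parcel-level maps the
    assumption holds.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for state in maps_a:
        a = np.asarray(maps_a[state], dtype=float).ravel()
        b = np.asarray(maps_b[state], dtype=float).ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 10:
            raise ValueError(f"<10 joint locations for state {state}")
        a, b = a[ok], b[ok]
        r_obs = stats.pearsonr(a, b)[0]
        az = (a - a.mean()) / a.std()
        bz = (b - b.mean()) / b.std()
        n = a.size
        perm_idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
        r_perm = (az[perm_idx] @ bz) / n
        p = (1.0 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (n_perm + 1.0)
        out[state] = {"r": float(r_obs), "p": float(p)}
    return out


def similarity_trend(r_by_state: dict[str, float] | np.ndarray) -> dict:
    """OLS of subgroup similarity on state index 1..8; two-sided slope test."""
    if isinstance(r_by_state, dict):
        items = sorted(r_by_state.items())
        idx = np.arange(1, len(items) + 1, dtype=float)
        r = np.array([v for _, v in items], dtype=float)
    else:
        r = np.asarray(r_by_state, dtype=float)
        idx = np.arange(1, r.size + 1, dtype=float)
    ok = np.isfinite(r)
    if ok.sum() < 3:
        raise ValueError("need >=3 states with defined similarity")
    res = stats.linregress(idx[ok], r[ok])
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "p": float(res.pvalue), "r": float(res.rvalue)}
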