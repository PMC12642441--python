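"""Regional homogeneity: Kendall's coefficient of concordance over voxel
neighborhoods, followed by standardization, NaN-aware Gaussian smoothing, and
parcel averaging.

Kendall's W measures agreement of the temporal rank orders of a voxel and its
spatial neighbors (cluster sizes 7/19/27); W = 1 means identical rank orders,
with mid-ranks and the standard tie correction so W stays in [0, 1] under
ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

__all__ = [
    "ReHoMap",
    "kendalls_w",
    "compute_reho",
    "zscore_map",
    "smooth_map",
    "parcel_average",
]

#: stencil offsets: 7 = faces, 19 = faces+edges, 27 = full 3x3x3 cube
_STENCILS: dict[int, list[tuple[int, int, int]]] = {}
for size, max_nonzero in ((7, 1), (19, 2), (27, 3)):
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i != 0) + (j != 0) + (k != 0) <= max_nonzero
    ]
    _STENCILS[size] = offs


@dataclass
class ReHoMap:
    """A 3D ReHo map at one processing stage (raw W, z-scored, or smoothed)."""

    values: np.ndarray
    mask: np.ndarray
    stage: str = "raw"  # raw | zscored | smoothed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")


def kendalls_w(block: np.ndarray) -> float:
    """Kendall's coefficient of concordance for an (m series x T points) block.

    Each series is ranked over time with mid-ranks; the tie-corrected
    denominator keeps W in [0, 1].  Returns NaN when the denominator is
    non-positive (all series constant).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError("block must be 2D (series x time)")
    m, T = block.shape
    if m < 2:
        raise ValueError("need at least 2 series")
    if T < 3:
        raise ValueError("need at least 3 time points")
    if not np.isfinite(block).all():
        raise ValueError("series must be finite")
    ranks = rankdata(block, axis=1)
    rank_sums = ranks.sum(axis=0)
    S = ((rank_sums - m * (T + 1) / 2.0) ** 2).sum()
    tie = _tie_corrections(block).sum()
    denom = m * m * (T**3 - T) - m * tie
    if denom <= 0:
        return float("nan")
    return float(12.0 * S / denom)


def _tie_corrections(x: np.ndarray) -> np.ndarray:
    """Per-row tie correction sum_g (t_g^3 - t_g) over tied groups, vectorized."""
    n, T = x.shape
    s = np.sort(x, axis=1)
    new_run = np.ones((n, T), dtype=bool)
    new_run[:, 1:] = s[:, 1:] != s[:, :-1]
    run_id = np.cumsum(new_run, axis=1) - 1
    flat = (np.arange(n)[:, None] * T + run_id).ravel()
    counts = np.bincount(flat, minlength=n * T).reshape(n, T)
    return (counts.astype(np.int64) ** 3 - counts).sum(axis=1).astype(float)


def compute_reho(image, cluster_size: int = 27, min_neighbors: int = 4) -> ReHoMap:
    """ReHo map: Kendall's W over each in-mask voxel and its stencil neighbors.

    Boundary voxels use their in-mask neighbors only; voxels with fewer than
    ``min_neighbors`` in-mask neighbors are set to NaN.
    """
    if cluster_size not in _STENCILS:
        raise ValueError(f"cluster_size must be one of {sorted(_STENCILS)}")
    data = np.asarray(image.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("compute_reho requires a 4D image")
    T = data.shape[-1]
    if T < 3:
        raise ValueError("need at least 3 time points")
    mask = np.asarray(image.mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    shape = data.shape[:3]
    # per-voxel temporal mid-ranks and tie corrections, zero outside mask
    ranks = np.zeros(data.shape)
    ties = np.zeros(shape)
    flat = data[mask]
    ranks[mask] = rankdata(flat, axis=1)
    ties[mask] = _tie_corrections(flat)
    valid = mask.astype(float)

    rank_acc = np.zeros(data.shape)
    count_acc = np.zeros(shape)
    tie_acc = np.zeros(shape)
    for off in _STENCILS[cluster_size]:
        src, dst = _shift_slices(shape, off)
        rank_acc[dst] += ranks[src]
        count_acc[dst] += valid[src]
        tie_acc[dst] += ties[src]

    m = count_acc
    with np.errstate(invalid="ignore", divide="ignore"):
        S = ((rank_acc - m[..., None] * (T + 1) / 2.0) ** 2).sum(axis=-1)
        denom = m * m * (T**3 - T) - m * tie_acc
        W = np.where(denom > 0, 12.0 * S / denom, np.nan)
    W[~mask] = np.nan
    W[m - 1 < min_neighbors] = np.nan  # m counts the center voxel
    return ReHoMap(values=W, mask=mask, stage="raw")


def _shift_slices(shape, offset):
    """Source/destination slice pairs implementing a zero-padded shift."""
    src, dst = [], []
    for dim, off in zip(shape, offset):
        if off == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif off > 0:
            src.append(slice(0, dim - off))
            dst.append(slice(off, dim))
        else:
            src.append(slice(-off, dim))
            dst.append(slice(0, dim + off))
    return tuple(src), tuple(dst)


def zscore_map(reho: ReHoMap) -> ReHoMap:
    """Standardize in-mask values to mean 0, SD 1 (ddof=1)."""
    vals = reho.values.copy()
    inside = reho.mask & np.isfinite(vals)
    x = vals[inside]
    if x.size < 2:
        raise ValueError("need >=2 in-mask values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance map cannot be standardized")
    vals[inside] = (x - x.mean()) / sd
    return ReHoMap(values=vals, mask=reho.mask, stage="zscored")


def smooth_map(reho: ReHoMap, fwhm_mm: float, voxel_size=(1.0, 1.0, 1.0)) -> ReHoMap:
    """NaN-aware Gaussian smoothing (sigma = fwhm / (2*sqrt(2 ln 2)) per axis).

    The map is renormalized by the smoothed valid-voxel indicator so masked-out
    or missing voxels neither bleed in nor attenuate edges; kernel truncated at
    4 sigma.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return ReHoMap(values=reho.values.copy(), mask=reho.mask, stage="smoothed")
    sigma_vox = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in voxel_size]
    vals = reho.values
    valid = reho.mask & np.isfinite(vals)
    filled = np.where(valid, vals, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma_vox, truncate=4.0)
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma_vox, truncate=4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out[~valid] = np.nan
    return ReHoMap(values=out, mask=reho.mask, stage="smoothed")


def parcel_average(reho: ReHoMap, parcellation) -> dict[int, float]:
    """Mean of in-mask, non-missing voxels per parcel; empty parcels get NaN."""
    labels = np.asarray(parcellation.labels)
    if labels.shape != reho.values.shape:
        raise ValueError("parcellation/map shape mismatch")
    valid = reho.mask & np.isfinite(reho.values)
    out: dict[int, float] = {}
    for pid in parcellation.parcel_ids:
        sel = (labels == pid) & valid
        out[int(pid)] = float(reho.values[sel].mean()) if sel.any() else float("nan")
    return out
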