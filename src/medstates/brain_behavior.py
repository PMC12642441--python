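"""Brain-experience coupling via partial least squares correlation (PLSC).

PLSC decomposes the cross-block correlation matrix R = Y_z^T X_z / (n-1)
by SVD; each latent variable pairs a brain salience pattern with a behavior
salience pattern, with covariance explained S_i^2 / sum S^2.  Inference uses
row permutations of Y (null singular values) and bootstrap resampling
(salience confidence intervals and bootstrap ratios); components are
retained by the Kaiser rule (explained covariance above the mean across
components).  Missing behavioral entries are completed beforehand by chained
equations with predictive mean matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trends import fdr_adjust

__all__ = [
    "PLSCResult",
    "mice_impute",
    "plsc_fit",
    "plsc_permutation",
    "plsc_bootstrap",
    "kaiser_retention",
    "latent_correlation",
    "univariate_factor_correlation",
    "FACTOR_STATES",
]

#: Phenomenology factors and the ordered states each one indexes.
FACTOR_STATES: dict[str, tuple[str, ...]] = {
    "bliss_joy": ("J1", "J2"),
    "contentment": ("J3",),
    "equanimity": ("J4",),
    "formlessness": ("J5", "J6", "J7", "J8"),
}


@dataclass
class PLSCResult:
    singular_values: np.ndarray
    cov_explained: np.ndarray  # percent, sums to 100
    brain_saliences: np.ndarray  # P x L
    behavior_saliences: np.ndarray  # Q x L
    latent_x: np.ndarray  # n x L
    latent_y: np.ndarray  # n x L
    perm_p: np.ndarray | None = None
    perm_q: np.ndarray | None = None
    boot_ci: tuple[np.ndarray, np.ndarray] | None = None  # brain low/high
    boot_ratio_brain: np.ndarray | None = None
    boot_ratio_behavior: np.ndarray | None = None
    behavior_boot_ci: tuple[np.ndarray, np.ndarray] | None = None
    retained: np.ndarray | None = None
    latent_r: np.ndarray | None = None
    latent_r_p: np.ndarray | None = None
    dropped_x: list = field(default_factory=list)
    dropped_y: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.singular_values.size


def _zscore(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    return Z, np.where(~keep)[0]


def mice_impute(table: pd.DataFrame, n_imputations: int = 5,
                n_iterations: int = 20, seed: int | None = None,
                k_donors: int = 5) -> pd.DataFrame:
    """Complete a numeric table by chained equations with predictive mean matching.

    Missing cells start at column means; each iteration regresses every
    incomplete column on all others (observed + current imputations) and
    replaces its missing entries with values drawn from the ``k_donors``
    observed rows whose predictions are closest (PMM).  ``n_imputations``
    independent chains are averaged element-wise.  Observed cells are never
    altered; a fixed seed reproduces the completion exactly.
    """
    df = table.copy()
    num_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    X = df[num_cols].to_numpy(dtype=float)
    miss = ~np.isfinite(X)
    if not miss.any():
        return df
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing")
    if miss.all(axis=1).any():
        raise ValueError("a row is entirely missing")
    frac = miss.mean(axis=0)
    if (frac > 0.5).any():
        warnings.warn("some columns have <50% observed values")
    root = np.random.SeedSequence(seed)
    completions = [_mice_chain(X, miss, n_iterations, k_donors,
                               np.random.default_rng(child))
                   for child in root.spawn(n_imputations)]
    X_done = np.mean(completions, axis=0)
    out = df.copy()
    out[num_cols] = X_done
    return out


def _mice_chain(X, miss, n_iterations, k_donors, rng):
    Z = X.copy()
    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        Z[miss[:, j], j] = col_means[j]
    incomplete = [j for j in range(X.shape[1]) if miss[:, j].any()]
    for _ in range(n_iterations):
        for j in incomplete:
            obs = ~miss[:, j]
            others = np.delete(Z, j, axis=1)
            A = np.column_stack([np.ones(len(Z)), others])
            coef, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
            pred = A @ coef
            pred_obs, y_obs = pred[obs], X[obs, j]
            for i in np.where(miss[:, j])[0]:
                k = min(k_donors, y_obs.size)
                donors = np.argsort(np.abs(pred_obs - pred[i]))[:k]
                Z[i, j] = y_obs[rng.choice(donors)]
    return Z


def plsc_fit(X: np.ndarray, Y: np.ndarray,
             n_components: int | None = None) -> PLSCResult:
    """Point-estimate PLSC of brain matrix X (n x P) and behavior Y (n x Q).

    Columns are z-scored; R = Y_z^T X_z / (n-1) is decomposed by SVD.  The
    number of components defaults to the number of behavioral variables,
    capped at rank(R).  Zero-variance columns are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2D with matching rows")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("missing values: impute before PLSC")
    Xz, drop_x = _zscore(X)
    Yz, drop_y = _zscore(Y)
    if drop_x.size or drop_y.size:
        warnings.warn(f"dropped zero-variance columns: X{drop_x.tolist()} "
                      f"Y{drop_y.tolist()}")
    R = Yz.T @ Xz / (n - 1)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    L = min(n_components or Yz.shape[1], rank)
    U, S, V = U[:, :L], S[:L], Vt[:L].T
    # deterministic sign: largest-|.| behavior salience entry positive
    for i in range(L):
        idx = np.argmax(np.abs(U[:, i]))
        if U[idx, i] < 0:
            U[:, i] *= -1
            V[:, i] *= -1
    total = float((np.linalg.svd(R, compute_uv=False) ** 2).sum())
    cov_expl = 100.0 * S**2 / total
    res = PLSCResult(singular_values=S, cov_explained=cov_expl,
                     brain_saliences=V, behavior_saliences=U,
                     latent_x=Xz @ V, latent_y=Yz @ U,
                     dropped_x=drop_x.tolist(), dropped_y=drop_y.tolist())
    res.retained = kaiser_retention(cov_expl)
    res.latent_r, res.latent_r_p = latent_correlation(res.latent_x, res.latent_y)
    return res


def plsc_permutation(X: np.ndarray, Y: np.ndarray, result: PLSCResult,
                     n_perm: int = 10000, seed: int | None = None) -> PLSCResult:
    """Permutation p-values for each latent variable's singular value.

    Rows of Y are permuted (X fixed); the i-th sorted null singular value is
    compared with the i-th observed one.  p = (1 + #{S_perm >= S_obs}) /
    (n_perm + 1), so the smallest attainable p is 1/(n_perm+1); q-values are
    BH across latent variables.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-values")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    Xz, _ = _zscore(np.asarray(X, dtype=float))
    Yz, _ = _zscore(np.asarray(Y, dtype=float))
    L = result.n_components
    S_obs = result.singular_values
    exceed = np.zeros(L)
    for _ in range(n_perm):
        Sp = np.linalg.svd(Yz[rng.permutation(n)].T @ Xz / (n - 1),
                           compute_uv=False)
        exceed += Sp[:L] >= S_obs
    result.perm_p = (1.0 + exceed) / (n_perm + 1.0)
    result.perm_q = fdr_adjust(result.perm_p)
    return result


def plsc_bootstrap(X: np.ndarray, Y: np.ndarray, result: PLSCResult,
                   n_boot: int = 10000, seed: int | None = None,
                   ci: float = 95.0) -> PLSCResult:
    """Bootstrap CIs and bootstrap ratios for brain and behavior saliences.

    Rows are resampled with replacement; each resample's saliences are
    sign-aligned to the original per latent variable before aggregation.
    Bootstrap ratio = original salience / bootstrap SE; |ratio| >= 1.96 is
    the conventional stability flag.  Degenerate resamples (constant column)
    are redrawn.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    L = result.n_components
    Vb = np.empty((n_boot, X.shape[1], L))
    Ub = np.empty((n_boot, Y.shape[1], L))
    b = 0
    redrawn = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        Xb, Yb = X[idx], Y[idx]
        if (Xb.std(axis=0) == 0).any() or (Yb.std(axis=0) == 0).any():
            redrawn += 1
            if redrawn > 100 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        fit = plsc_fit(Xb, Yb, n_components=L)
        Lb = fit.n_components
        V = np.zeros((X.shape[1], L))
        U = np.zeros((Y.shape[1], L))
        V[:, :Lb] = fit.brain_saliences
        U[:, :Lb] = fit.behavior_saliences
        for i in range(Lb):  # align signs to the original solution
            s = np.sign(V[:, i] @ result.brain_saliences[:, i]
                        + U[:, i] @ result.behavior_saliences[:, i])
            if s < 0:
                V[:, i] *= -1
                U[:, i] *= -1
        Vb[b], Ub[b] = V, U
        b += 1
    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
    result.boot_ci = (np.percentile(Vb, lo, axis=0), np.percentile(Vb, hi, axis=0))
    result.behavior_boot_ci = (np.percentile(Ub, lo, axis=0),
                               np.percentile(Ub, hi, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        result.boot_ratio_brain = result.brain_saliences / Vb.std(axis=0, ddof=1)
        result.boot_ratio_behavior = (result.behavior_saliences
                                      / Ub.std(axis=0, ddof=1))
    return result


def kaiser_retention(cov_explained: np.ndarray) -> np.ndarray:
    """Retain latent variables whose explained covariance exceeds the mean
    across components (strict inequality)."""
    v = np.asarray(cov_explained, dtype=float)
    if (v < 0).any():
        raise ValueError("explained covariance must be nonnegative")
    return v > v.mean()


def latent_correlation(L_X: np.ndarray, L_Y: np.ndarray):
    """Pearson r (with two-sided p) between paired latent scores, per LV."""
    L_X, L_Y = np.atleast_2d(L_X.T).T, np.atleast_2d(L_Y.T).T
    rs, ps = [], []
    for i in range(L_X.shape[1]):
        x, y = L_X[:, i], L_Y[:, i]
        if x.std() == 0 or y.std() == 0:
            rs.append(np.nan)
            ps.append(np.nan)
        else:
            r, p = stats.pearsonr(x, y)
            rs.append(r)
            ps.append(p)
    return np.array(rs), np.array(ps)


def univariate_factor_correlation(metrics: pd.DataFrame, ratings: pd.Series,
                                  min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlation of each ROI metric with one factor's ratings.

    ``metrics`` is rows x ROIs aligned with ``ratings`` (participant x state
    rows restricted to the factor's state set).  FDR is applied within the
    ROI family of this factor; ROIs with fewer than ``min_pairs`` complete
    pairs or zero variance are reported as missing.
    """
    y = np.asarray(ratings, dtype=float)
    rows = []
    for col in metrics.columns:
        x = metrics[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs or x[ok].std() == 0 or y[ok].std() == 0:
            rows.append({"roi": col, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"roi": col, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out
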