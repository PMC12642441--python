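"""State-trajectory inference across the ordered meditation states.

Each neuroimaging metric is modelled with a random-intercept linear mixed
model across the eight ordered states, with centered orthonormal polynomial
contrasts up to the cubic.  Non-significant highest-degree terms are removed
iteratively (never below the linear term).  Condition-vs-control contrasts
use the same machinery with a categorical state factor and estimated marginal
means, with a two-level FDR (within model, then across metrics).

The mixed model is fit by profiled restricted maximum likelihood: for a
compound-symmetric (random intercept) covariance the per-evaluation GLS
quantities are closed form, leaving a 1-D optimization over the variance
ratio.  This makes the large calibration simulations tractable; the solver
agrees with a general-purpose mixed-model implementation (see tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import COMPOSITE_CONTROL, CONTROLS, STATES

__all__ = [
    "TrendResult",
    "ContrastResult",
    "average_sessions",
    "composite_control",
    "orthogonal_poly_codes",
    "fit_trend_lmm",
    "fit_condition_contrasts",
    "control_vs_control",
    "fdr_adjust",
    "fit_trend_table",
]


@dataclass
class TrendResult:
    """Polynomial-trend mixed-model fit for one metric."""

    metric: str
    retained_degree: int
    beta: np.ndarray  # coefficients for degrees 1..retained_degree
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    intercept: float
    sigma_participant: float  # random-intercept variance
    sigma_residual: float
    model_p: float
    df_resid: float
    q: np.ndarray | None = None
    full_fit: dict | None = None  # audit: un-reduced max_degree fit
    fallback_ols: bool = False


@dataclass
class ContrastResult:
    """Per-condition estimated marginal means and contrasts vs the control."""

    metric: str
    conditions: list[str]
    emmeans: np.ndarray
    contrast_conditions: list[str]
    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q_within: np.ndarray
    q_across: np.ndarray | None = None
    sigma_participant: float = 0.0
    sigma_residual: float = 0.0


def average_sessions(rows: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Mean over sessions per participant x condition x metric."""
    keys = [c for c in ("participant", "condition", "metric") if c in rows.columns]
    return (rows.groupby(keys, as_index=False, sort=False)[value_col]
            .mean())


def composite_control(rows: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Append composite-control rows (mean of counting and memory).

    The original control rows are retained for the control-vs-control
    analysis.  Participants (per metric) with neither control are flagged via
    warning and get no composite row.
    """
    ctrl = rows[rows["condition"].isin(CONTROLS)]
    keys = [c for c in ("participant", "metric") if c in rows.columns]
    comp = ctrl.groupby(keys, as_index=False, sort=False)[value_col].mean()
    comp["condition"] = COMPOSITE_CONTROL
    n_ctrl = ctrl.groupby(keys, sort=False)["condition"].nunique()
    if (n_ctrl < 2).any():
        warnings.warn("some participants have only one control condition; "
                      "composite uses the available one")
    missing = (rows.groupby(keys, sort=False).size().index
               .difference(comp.set_index(keys).index))
    if len(missing):
        warnings.warn(f"participants excluded from contrasts (no controls): "
                      f"{list(missing)}")
    return pd.concat([rows, comp[rows.columns.intersection(comp.columns)]],
                     ignore_index=True)


def orthogonal_poly_codes(n_levels: int, max_degree: int) -> np.ndarray:
    """Orthonormal, zero-sum polynomial contrast columns (degree 1..max_degree).

    Built by QR of the centered-level Vandermonde matrix; signs fixed so the
    value at the highest level is positive (the R ``contr.poly`` convention).
    """
    if max_degree >= n_levels:
        raise ValueError("max_degree must be < n_levels")
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    x = np.arange(n_levels, dtype=float)
    x -= x.mean()
    V = np.vander(x, max_degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    Q = Q[:, 1:]
    Q = Q * np.where(Q[-1] > 0, 1.0, -1.0)
    return Q


# --------------------------------------------------------------------------
# profiled-REML random-intercept engine


def _reml_random_intercept(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """REML fit of y = X b + u_group + e with compound-symmetric covariance.

    Returns (beta, cov_beta, sigma_u2, sigma_e2).  The variance ratio
    theta = sigma_u2 / sigma_e2 is profiled out and optimized in log space.
    """
    N, p = X.shape
    uniq, gidx = np.unique(groups, return_inverse=True)
    G = uniq.size
    n_i = np.bincount(gidx).astype(float)
    Xs = np.zeros((G, p))
    np.add.at(Xs, gidx, X)
    ys = np.bincount(gidx, weights=y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def quantities(theta):
        c = theta / (1.0 + n_i * theta)
        XtViX = XtX - (Xs * c[:, None]).T @ Xs
        XtViy = Xty - (Xs * c[:, None]).T @ ys
        ytViy = yty - float(c @ (ys**2))
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(ytViy - float(beta @ XtViy), 1e-300)
        return c, XtViX, beta, rss

    def neg2_reml(log_theta):
        theta = np.exp(log_theta)
        c, XtViX, beta, rss = quantities(theta)
        sign, logdet = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return (np.log1p(n_i * theta).sum() + logdet + (N - p) * np.log(rss))

    res = optimize.minimize_scalar(neg2_reml, bounds=(-25.0, 25.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    theta = float(np.exp(res.x))
    # prefer the theta -> 0 boundary when it fits at least as well
    if neg2_reml(-300.0) <= res.fun + 1e-10:
        theta = 0.0
    c, XtViX, beta, rss = quantities(theta)
    sigma_e2 = rss / (N - p)
    cov_beta = np.linalg.inv(XtViX) * sigma_e2
    return beta, cov_beta, theta * sigma_e2, sigma_e2


def _as_long(values, n_levels: int):
    """Coerce (participants x levels) array or long DataFrame to arrays."""
    if isinstance(values, pd.DataFrame):
        part = values["participant"].to_numpy()
        level = values["state"].to_numpy().astype(int) - 1
        y = values["value"].to_numpy(dtype=float)
        return y, level, part
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != n_levels:
        raise ValueError(f"expected participants x {n_levels} array")
    n_part = arr.shape[0]
    y = arr.ravel()
    level = np.tile(np.arange(n_levels), n_part)
    part = np.repeat(np.arange(n_part), n_levels)
    keep = np.isfinite(y)
    return y[keep], level[keep], part[keep]


def fit_trend_lmm(values, max_degree: int = 3, alpha: float = 0.05,
                  n_states: int = 8, metric: str = "") -> TrendResult:
    """Polynomial-trend mixed model with iterative degree reduction.

    ``values`` is either a (participants x states) array or a long DataFrame
    with columns participant/state/value.  Fits start at ``max_degree``;
    while the highest-degree coefficient is non-significant at ``alpha`` the
    degree is reduced by one, never below the linear term.  The un-reduced
    fit is kept for audit.  t tests use residual degrees of freedom
    N_obs - N_participants - D.
    """
    y, level, part = _as_long(values, n_states)
    n_part = np.unique(part).size
    if n_part < 3:
        raise ValueError("need at least 3 participants")
    levels_present = np.unique(level).size
    max_degree = min(max_degree, levels_present - 2)
    if max_degree < 1:
        raise ValueError("too few states for a linear trend")
    codes = orthogonal_poly_codes(n_states, max_degree)

    full_fit = None
    D = max_degree
    while True:
        out = _fit_poly(y, level, part, codes, D, metric)
        if full_fit is None:
            full_fit = {"degree": D, "beta": out["beta"], "p": out["p"]}
        if D == 1 or out["p"][-1] < alpha:
            break
        D -= 1
    return TrendResult(metric=metric, retained_degree=D, beta=out["beta"],
                       se=out["se"], t=out["t"], p=out["p"],
                       intercept=out["intercept"],
                       sigma_participant=out["sigma_u2"],
                       sigma_residual=out["sigma_e2"],
                       model_p=out["model_p"], df_resid=out["df"],
                       full_fit=full_fit, fallback_ols=out["fallback"])


def _fit_poly(y, level, part, codes, D, metric):
    N = y.size
    X = np.column_stack([np.ones(N), codes[level, :D]])
    fallback = False
    try:
        beta, cov, s_u2, s_e2 = _reml_random_intercept(X, y, part)
    except np.linalg.LinAlgError:
        # within-participant OLS fallback: demean per participant
        warnings.warn(f"mixed model failed for {metric!r}; OLS fallback")
        fallback = True
        yd = y - np.bincount(part, weights=y)[part] / np.bincount(part)[part]
        Xc = X[:, 1:]
        beta_c, res, *_ = np.linalg.lstsq(Xc, yd, rcond=None)
        dfr = N - np.unique(part).size - D
        s_e2 = float(((yd - Xc @ beta_c) ** 2).sum() / dfr)
        cov_c = np.linalg.inv(Xc.T @ Xc) * s_e2
        beta = np.concatenate([[y.mean()], beta_c])
        cov = np.zeros((D + 1, D + 1))
        cov[1:, 1:] = cov_c
        cov[0, 0] = s_e2 / N
        s_u2 = 0.0
    df = N - np.unique(part).size - D
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    # joint Wald F test over the polynomial terms = model significance
    bp, cp = beta[1:], cov[1:, 1:]
    F = float(bp @ np.linalg.solve(cp, bp)) / D
    model_p = float(stats.f.sf(F, D, df))
    return {"beta": beta[1:], "se": se[1:], "t": t[1:], "p": p[1:],
            "intercept": float(beta[0]), "sigma_u2": float(s_u2),
            "sigma_e2": float(s_e2), "model_p": model_p, "df": df,
            "fallback": fallback}


def fit_trend_table(table: pd.DataFrame, max_degree: int = 3,
                    alpha: float = 0.05, fdr_on: str = "model_p",
                    n_states: int = 8) -> pd.DataFrame:
    """Fit trends for every metric in a long table and FDR-adjust across metrics.

    The table needs columns participant/state/value/metric.  Returns one row
    per metric with retained degree, coefficients, p-values and q-values
    (BH across metrics on ``fdr_on`` plus per-degree q columns).
    """
    rows = []
    for metric, grp in table.groupby("metric", sort=False):
        res = fit_trend_lmm(grp[["participant", "state", "value"]],
                            max_degree=max_degree, alpha=alpha,
                            n_states=n_states, metric=str(metric))
        row = {"metric": str(metric), "retained_degree": res.retained_degree,
               "model_p": res.model_p,
               "sigma_participant": res.sigma_participant,
               "sigma_residual": res.sigma_residual}
        for d in range(1, max_degree + 1):
            has = d <= res.retained_degree
            row[f"beta{d}"] = res.beta[d - 1] if has else np.nan
            row[f"p{d}"] = res.p[d - 1] if has else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df["model_q"] = fdr_adjust(df["model_p"].to_numpy())
    for d in range(1, max_degree + 1):
        df[f"q{d}"] = fdr_adjust(df[f"p{d}"].to_numpy())
    return df


def fit_condition_contrasts(table: pd.DataFrame, metric: str = "",
                            control: str = COMPOSITE_CONTROL) -> ContrastResult:
    """Categorical-state mixed model with per-state contrasts vs the control.

    Estimated marginal means come from the fitted fixed effects (equal to raw
    condition means in a balanced design); contrasts are state minus control
    with FDR within the model's contrast family.
    """
    df = table[table["condition"].isin(STATES + (control,))]
    conds = [control] + [s for s in STATES if s in set(df["condition"])]
    cidx = df["condition"].map({c: i for i, c in enumerate(conds)}).to_numpy()
    y = df["value"].to_numpy(dtype=float)
    part = df["participant"].to_numpy()
    keep = np.isfinite(y)
    y, cidx, part = y[keep], cidx[keep], part[keep]
    n_cond = len(conds)
    X = np.zeros((y.size, n_cond))
    X[:, 0] = 1.0
    for j in range(1, n_cond):
        X[cidx == j, j] = 1.0
    beta, cov, s_u2, s_e2 = _reml_random_intercept(X, y, part)
    dfree = y.size - np.unique(part).size - (n_cond - 1)
    emm = np.concatenate([[beta[0]], beta[0] + beta[1:]])
    est = beta[1:]
    se = np.sqrt(np.diag(cov)[1:])
    t = est / se
    p = 2 * stats.t.sf(np.abs(t), dfree)
    return ContrastResult(metric=metric, conditions=conds, emmeans=emm,
                          contrast_conditions=conds[1:], estimates=est,
                          se=se, t=t, p=p, q_within=fdr_adjust(p),
                          sigma_participant=float(s_u2),
                          sigma_residual=float(s_e2))


def contrasts_across_fdr(results: list[ContrastResult]) -> list[ContrastResult]:
    """Second-level FDR across all models' contrasts (two-level correction)."""
    all_p = np.concatenate([r.p for r in results])
    all_q = fdr_adjust(all_p)
    pos = 0
    for r in results:
        r.q_across = all_q[pos:pos + r.p.size]
        pos += r.p.size
    return results


def control_vs_control(table: pd.DataFrame, metric: str = "") -> dict:
    """Counting-vs-memory contrast from a random-intercept model for one metric."""
    df = table[table["condition"].isin(CONTROLS)]
    y = df["value"].to_numpy(dtype=float)
    part = df["participant"].to_numpy()
    is_mem = (df["condition"] == "memory").to_numpy().astype(float)
    keep = np.isfinite(y)
    y, part, is_mem = y[keep], part[keep], is_mem[keep]
    X = np.column_stack([np.ones(y.size), is_mem])
    beta, cov, s_u2, s_e2 = _reml_random_intercept(X, y, part)
    dfree = y.size - np.unique(part).size - 1
    se = float(np.sqrt(cov[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), dfree))
    return {"metric": metric, "estimate": float(beta[1]), "se": se, "t": t,
            "p": p, "sigma_participant": float(s_u2),
            "sigma_residual": float(s_e2)}


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaNs pass through unadjusted."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
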