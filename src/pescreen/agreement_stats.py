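"""Continuous-agreement statistics for the two balloon-validity ratios.

The experimental ratio (from P0.1 maneuvers) is compared to the reference
ratio (from prolonged occlusions) with:

* simple linear regression (slope, intercept, R-squared, F-test p);
* Bland-Altman analysis (bias, its 95 % t-interval, and the 95 % limits of
  agreement bias +/- 1.96 * sd of the paired differences);
* a Gaussian generalized estimating equation (GEE) with identity link,
  clustering by patient, an exchangeable working correlation, and robust
  (sandwich) standard errors — the marginal slope is unbiased for the
  association while the sandwich variance absorbs the within-patient
  correlation of repeated measurements;
* per-subgroup independent regressions (R-squared per patient stratum).

The GEE solver is written out explicitly (iterated cluster-weighted GLS
with the moment estimator of the exchangeable correlation); the statsmodels
implementation serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "GEEResult",
    "linear_regression",
    "bland_altman",
    "gee_gaussian_exchangeable",
    "subgroup_r2",
    "subgroup_regressions",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Input has no usable variation (e.g. zero variance in the predictor)."""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    bias_ci: tuple[float, float]  # 95 % t-interval for the mean difference
    loa: tuple[float, float]  # bias +/- 1.96 * sd(differences)
    sd_diff: float
    n: int
    n_outside: int  # differences strictly beyond the limits of agreement


@dataclass(frozen=True)
class GEEResult:
    beta: float  # slope
    intercept: float
    robust_se: float  # sandwich SE of the slope
    ci95: tuple[float, float]  # beta +/- 1.96 * robust_se
    alpha_exch: float  # estimated exchangeable correlation
    scale: float
    n_clusters: int
    n_obs: int
    n_iter: int
    converged: bool


def _as_xy(x: Sequence[float], y: Sequence[float], min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x``.

    R-squared is 1 - SSE/SST; the p-value is the F-test of zero slope,
    which for simple regression equals the two-sided t-test of the slope.
    """
    x, y = _as_xy(x, y)
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in x: slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement of method ``y`` against method ``x``.

    Differences are ``y - x``; the limits of agreement are
    ``bias +/- 1.96 * sd`` (sample sd, denominator n-1) and the bias CI uses
    the t distribution with n-1 degrees of freedom.
    """
    x, y = _as_xy(x, y)
    d = y - x
    n = d.size
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    n_outside = int(np.sum((d < loa[0]) | (d > loa[1])))
    return BlandAltmanResult(
        bias=bias,
        bias_ci=(bias - half, bias + half),
        loa=loa,
        sd_diff=sd,
        n=n,
        n_outside=n_outside,
    )


# ---------------------------------------------------------------------------
# GEE


def _exchangeable_solve(
    X: np.ndarray, resid_or_y: np.ndarray, sizes: np.ndarray, alpha: float
):
    """Accumulate sum_i X_i' R_i^{-1} z_i and X_i' R_i^{-1} X_i using the
    closed-form inverse of the exchangeable correlation matrix
    R = (1-a) I + a J:  R^{-1} = [I - a/(1+(n-1)a) J] / (1-a)."""
    p = X.shape[1]
    XtWX = np.zeros((p, p))
    XtWz = np.zeros(p)
    start = 0
    for m in sizes:
        Xi = X[start : start + m]
        zi = resid_or_y[start : start + m]
        c = alpha / (1.0 + (m - 1) * alpha)
        XtWX += (Xi.T @ Xi - c * np.outer(Xi.sum(0), Xi.sum(0))) / (1.0 - alpha)
        XtWz += (Xi.T @ zi - c * Xi.sum(0) * zi.sum()) / (1.0 - alpha)
        start += m
    return XtWX, XtWz


def gee_gaussian_exchangeable(
    y: Sequence[float],
    x: Sequence[float],
    cluster_ids: Sequence,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GEEResult:
    """Gaussian GEE of ``y`` on ``x`` with identity link, exchangeable
    working correlation within clusters, and sandwich standard errors.

    Iterates (1) cluster-weighted GLS for (intercept, slope) given the
    working correlation alpha and (2) the moment estimator of alpha from
    within-cluster cross-products of standardized residuals, until the
    coefficient change falls below ``tol``.  With every cluster of size 1
    the fit reduces exactly to OLS with a heteroskedasticity-robust
    (HC-type) sandwich.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ids = np.asarray(cluster_ids)
    if not (y.shape == x.shape == ids.shape) or y.ndim != 1:
        raise ValueError("y, x and cluster_ids must be 1-d and of equal length")
    # stable sort by cluster so members are contiguous
    order = np.argsort(ids, kind="stable")
    y, x, ids = y[order], x[order], ids[order]
    _, sizes = np.unique(ids, return_counts=True)
    # np.unique sorts; recover contiguous group sizes in data order
    boundaries = np.flatnonzero(np.concatenate(([True], ids[1:] != ids[:-1])))
    sizes = np.diff(np.concatenate((boundaries, [ids.size])))
    n_clusters = sizes.size
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    X = np.column_stack((np.ones_like(x), x))
    N, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDataError("singular design matrix")

    beta = np.linalg.lstsq(X, y, rcond=None)[0]  # OLS start
    alpha = 0.0
    max_m = int(sizes.max())
    alpha_floor = -1.0 / (max_m - 1) + 1e-6 if max_m > 1 else 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        scale = float(resid @ resid) / (N - p)
        # moment estimator of the exchangeable correlation
        n_pairs = int((sizes * (sizes - 1) // 2).sum())
        if n_pairs > p and scale > 0:
            cross = 0.0
            start = 0
            for m in sizes:
                r = resid[start : start + m]
                cross += (r.sum() ** 2 - (r**2).sum()) / 2.0
                start += m
            alpha = cross / ((n_pairs - p) * scale)
            alpha = float(np.clip(alpha, alpha_floor, 1.0 - 1e-6))
        else:
            alpha = 0.0
        XtWX, XtWy = _exchangeable_solve(X, y, sizes, alpha)
        beta_new = np.linalg.solve(XtWX, XtWy)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    resid = y - X @ beta
    scale = float(resid @ resid) / (N - p)
    # sandwich: bread = (sum X'V^-1 X)^-1, meat = sum of score outer products
    XtWX, _ = _exchangeable_solve(X, y, sizes, alpha)
    bread = np.linalg.inv(XtWX / scale)
    meat = np.zeros((p, p))
    start = 0
    for m in sizes:
        Xi = X[start : start + m]
        ri = resid[start : start + m]
        c = alpha / (1.0 + (m - 1) * alpha)
        score = (Xi.T @ ri - c * Xi.sum(0) * ri.sum()) / ((1.0 - alpha) * scale)
        meat += np.outer(score, score)
        start += m
    cov = bread @ meat @ bread
    se = float(np.sqrt(cov[1, 1]))
    return GEEResult(
        beta=float(beta[1]),
        intercept=float(beta[0]),
        robust_se=se,
        ci95=(float(beta[1] - 1.96 * se), float(beta[1] + 1.96 * se)),
        alpha_exch=float(alpha),
        scale=scale,
        n_clusters=int(n_clusters),
        n_obs=int(N),
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# subgroup regressions


def subgroup_r2(
    x: Sequence[float],
    y: Sequence[float],
    groups: Sequence,
    min_n: int = 3,
) -> dict:
    """Independent OLS per group; groups below ``min_n`` are flagged, skipped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    out: dict = {}
    for g in pd.unique(groups):
        mask = groups == g
        if int(mask.sum()) < min_n:
            out[g] = {"skipped": True, "n": int(mask.sum())}
            continue
        try:
            res = linear_regression(x[mask], y[mask])
        except DegenerateDataError:
            out[g] = {"skipped": True, "n": int(mask.sum())}
            continue
        out[g] = res
    return out


STANDARD_GROUPINGS = (
    "age_median",
    "sex",
    "bmi_median",
    "primary_resp_failure",
    "pulm_comorbidity",
)


def _grouping_labels(cov: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "age_median":
        med = cov["age"].median()
        return np.where(cov["age"] < med, "age<median", "age>=median")
    if grouping == "bmi_median":
        med = cov["bmi"].median()
        return np.where(cov["bmi"] < med, "bmi<median", "bmi>=median")
    if grouping == "sex":
        return cov["sex"].to_numpy()
    if grouping in ("primary_resp_failure", "pulm_comorbidity"):
        return np.where(cov[grouping], "yes", "no")
    raise ValueError(f"unknown grouping {grouping!r}")


def subgroup_regressions(
    pairs_df: pd.DataFrame,
    covariates: pd.DataFrame,
    groupings: Sequence[str] = STANDARD_GROUPINGS,
    x_col: str = "ratio_occ",
    y_col: str = "ratio_p01",
) -> dict[str, dict]:
    """Per-baseline-stratum regressions of the experimental on the reference
    ratio (pairs joined to per-patient covariates on ``patient_id``)."""
    cov = covariates.set_index("patient_id")
    out: dict[str, dict] = {}
    for grouping in groupings:
        labels_by_pid = pd.Series(
            _grouping_labels(cov.reset_index(), grouping),
            index=cov.index,
        )
        labels = pairs_df["patient_id"].map(labels_by_pid)
        out[grouping] = subgroup_r2(
            pairs_df[x_col], pairs_df[y_col], labels.to_numpy()
        )
    return out
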