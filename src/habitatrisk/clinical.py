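"""Clinical and immunological feature screening.

Covers the tabular arm of the risk model: iterative variance-inflation-
factor (VIF) screening for multicollinearity, multivariate logistic
regression reported as odds ratios with Wald confidence intervals, and the
two-way random absolute-agreement single-measure intraclass correlation
coefficient, ICC(2,1), for inter-rater segmentation agreement.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "vif_screen",
    "fit_multivariate_logistic",
    "icc_agreement",
    "LogisticFit",
    "ICCResult",
    "VIF_INF",
]

#: Sentinel VIF for perfect collinearity (R^2 == 1).
VIF_INF = np.inf


def _vif_one(x: np.ndarray, j: int) -> float:
    """VIF_j = 1 / (1 - R^2) from regressing column j on the others."""
    y = x[:, j]
    others = np.delete(x, j, axis=1)
    a = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss <= 0:
        return VIF_INF
    r2 = 1.0 - (resid ** 2).sum() / tss
    if r2 >= 1.0 - 1e-12:
        return VIF_INF
    return 1.0 / (1.0 - r2)


def vif_screen(table: pd.DataFrame, threshold: float = 5.0):
    """Iteratively remove multicollinear columns by VIF.

    At each pass the VIF of every remaining column is computed and the
    worst offender above ``threshold`` is removed (ties broken by column
    name so the result is invariant to column permutation); perfectly
    collinear columns carry an infinite sentinel and go first. Stops when
    all VIFs are at or below the threshold.

    Returns ``(retained_columns, vif_table)`` where ``vif_table`` holds
    the final VIF per retained column and the VIF each removed column had
    when it was removed.
    """
    df = table.select_dtypes(include=[np.number])
    if df.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 numeric columns")
    if len(df) <= df.shape[1]:
        raise ValueError("VIF screening needs n > number of columns")
    cols = sorted(df.columns)          # deterministic base order
    removed: dict[str, float] = {}
    while len(cols) >= 2:
        x = df[cols].to_numpy(dtype=float)
        vifs = {c: _vif_one(x, i) for i, c in enumerate(cols)}
        worst = max(cols, key=lambda c: (vifs[c], c))
        if vifs[worst] > threshold:
            removed[worst] = vifs[worst]
            cols = [c for c in cols if c != worst]
        else:
            break
    final = {c: vifs[c] for c in cols} if len(cols) >= 2 else {}
    retained = [c for c in table.columns if c in set(cols)]
    vif_table = pd.Series({**final, **removed}, name="VIF")
    return retained, vif_table


@dataclass(frozen=True)
class LogisticFit:
    """Multivariate logistic regression summary (Table-style)."""

    params: pd.Series            # beta per covariate (incl. intercept)
    bse: pd.Series               # standard errors
    odds_ratio: pd.Series        # exp(beta)
    ci_low: pd.Series            # exp(beta - 1.96 SE)
    ci_high: pd.Series           # exp(beta + 1.96 SE)
    pvalues: pd.Series           # Wald p per covariate
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.params,
            "OR": self.odds_ratio,
            "CI_low": self.ci_low,
            "CI_high": self.ci_high,
            "p": self.pvalues,
        })


def fit_multivariate_logistic(table: pd.DataFrame, labels,
                              standardize: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Continuous covariates (more than two distinct values) are standardized
    by default so odds ratios read per SD; binary covariates enter as-is.
    Quasi-separation is reported through the convergence flag rather than
    silently returned.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    df = table.select_dtypes(include=[np.number]).copy()
    if df.shape[1] == 0:
        raise ValueError("no numeric covariates")
    for c in df.columns:
        col = df[c].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {c!r} has no variation")
        if standardize and len(np.unique(col)) > 2:
            df[c] = (col - col.mean()) / col.std()
    x = sm.add_constant(df, has_constant="add")
    model = sm.Logit(y, x)
    try:
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        # Newton fails under (quasi-)separation; BFGS still yields the
        # diverging path, reported with an explicit non-convergence flag.
        res = model.fit(method="bfgs", disp=0, maxiter=500)
        converged = False
    # Huge or undefined standard errors betray (quasi-)separation.
    bse_arr = np.asarray(res.bse, dtype=float)
    if np.any(~np.isfinite(bse_arr)) or np.any(bse_arr > 1e3):
        converged = False
    params = pd.Series(res.params, index=x.columns)
    bse = pd.Series(res.bse, index=x.columns)
    return LogisticFit(
        params=params,
        bse=bse,
        odds_ratio=np.exp(params),
        ci_low=np.exp(params - 1.96 * bse),
        ci_high=np.exp(params + 1.96 * bse),
        pvalues=pd.Series(res.pvalues, index=x.columns),
        converged=converged,
    )


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_raters: float
    ms_error: float


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n_subjects, n_raters). From the two-way ANOVA mean
    squares (rows MSR, raters MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval follows the F-distribution construction of
    Shrout & Fleiss / McGraw & Wong.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (n_subjects, n_raters>=2)")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong CI for ICC(A,1).
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a):
        v_num = (a * msc + b * mse) ** 2
        v_den = ((a * msc) ** 2 / (k - 1)
                 + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = v_num / v_den if v_den > 0 else 1.0
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr)
    else:
        lo = hi = 1.0
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     ms_rows=float(msr), ms_raters=float(msc),
                     ms_error=float(mse))
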