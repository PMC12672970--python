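"""Three-step radiomic feature selection.

The chain filters a feature block with binary labels through

1. a two-sided Mann-Whitney U test (keep p < alpha),
2. a greedy Spearman correlation filter that walks features in ascending
   p-value order and drops any feature correlated above a threshold with
   one already kept,
3. logistic LASSO with stratified 10-fold cross-validation, keeping the
   features with nonzero coefficients at the deviance-minimizing penalty.

Each stage only removes columns; subject rows are never touched, and a
fixed seed makes folds — and therefore the selection — deterministic.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ._types import FeatureBlock

__all__ = ["mwu_filter", "correlation_filter", "lasso_select", "select_chain"]


def _check_binary(labels):
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("binary labels required")
    return y


def mwu_pvalues(block: FeatureBlock, labels) -> pd.Series:
    """Two-sided Mann-Whitney U p-value per feature (midranks for ties).

    Constant features have identical distributions by construction and
    report p = 1.
    """
    y = _check_binary(labels)
    classes = np.unique(y)
    x = block.data.to_numpy(dtype=float)
    a = x[y == classes[0]]
    b = x[y == classes[1]]
    ps = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if np.ptp(x[:, j]) == 0:
            ps[j] = 1.0
            continue
        ps[j] = stats.mannwhitneyu(a[:, j], b[:, j],
                                   alternative="two-sided").pvalue
    return pd.Series(ps, index=block.data.columns)


def mwu_filter(block: FeatureBlock, labels, alpha: float = 0.05):
    """Keep features whose Mann-Whitney p-value is below ``alpha``.

    Returns ``(filtered_block, pvalues)``.
    """
    ps = mwu_pvalues(block, labels)
    kept = ps.index[ps < alpha]
    return block.subset(kept), ps


def correlation_filter(block: FeatureBlock, r_threshold: float = 0.90,
                       order: pd.Series | None = None):
    """Greedy redundancy removal by absolute Spearman correlation.

    Features are visited in ascending ``order`` (Mann-Whitney p-values when
    given, otherwise the block's column order); a feature is dropped when
    |rho| > ``r_threshold`` against any feature already kept, so of a
    correlated group only its most significant member survives.
    """
    cols = list(block.data.columns)
    if len(cols) < 2:
        return block
    if order is not None:
        cols = list(order.loc[cols].sort_values(kind="stable").index)
    rho = block.data[cols].rank().corr().abs().to_numpy()
    kept_idx: list[int] = []
    for j in range(len(cols)):
        if all(rho[j, i] <= r_threshold for i in kept_idx):
            kept_idx.append(j)
    kept = [cols[i] for i in kept_idx]
    # Preserve original column order in the output block.
    kept = [c for c in block.data.columns if c in set(kept)]
    return block.subset(kept)


#: Default penalty grid (inverse regularization C on z-scored features).
#: Beyond C ~ 10 the path approaches the unpenalized fit — not a selection
#: regime — and liblinear becomes slow on near-separable data.
DEFAULT_PENALTY_GRID = np.logspace(-3, 1, 30)


def lasso_select(block: FeatureBlock, labels, n_folds: int = 10,
                 seed: int = 0, penalty_grid=None, rule: str = "min"):
    """Logistic LASSO selection with stratified k-fold cross-validation.

    Features are standardized internally; the penalty path is scored by
    cross-validated deviance. ``rule='min'`` (default) keeps the deviance
    minimizer, which retains the most signal for downstream fusion but
    over-selects relative to ``rule='1se'``, the sparser
    one-standard-error alternative. Returns ``(selected_block,
    coefficients)`` on the standardized scale; selecting nothing returns
    an empty block with a warning.
    """
    y = _check_binary(labels)
    if block.n_subjects < n_folds:
        raise ValueError("need at least n_folds subjects")
    cs = np.sort(np.asarray(
        DEFAULT_PENALTY_GRID if penalty_grid is None else penalty_grid,
        dtype=float))
    x = StandardScaler().fit_transform(block.data.to_numpy(dtype=float))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = LogisticRegressionCV(
            Cs=cs,
            cv=cv,
            l1_ratios=(1.0,),
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=1000,
            random_state=seed,
        )
        model.fit(x, y)
        if rule == "min":
            coef_vec = model.coef_[0]
        elif rule == "1se":
            scores = np.squeeze(np.asarray(model.scores_[y.max()]))
            mean = scores.mean(axis=0)
            se = scores.std(axis=0) / np.sqrt(scores.shape[0])
            best = int(mean.argmax())
            ok = np.flatnonzero(mean >= mean[best] - se[best])
            c_1se = cs[ok[0]]       # strongest penalty within one SE
            from sklearn.linear_model import LogisticRegression

            refit = LogisticRegression(C=c_1se, l1_ratio=1.0,
                                       solver="liblinear", max_iter=1000,
                                       random_state=seed).fit(x, y)
            coef_vec = refit.coef_[0]
        else:
            raise ValueError("rule must be 'min' or '1se'")
    coef = pd.Series(coef_vec, index=block.data.columns)
    kept = coef.index[coef != 0.0]
    if len(kept) == 0:
        warnings.warn("LASSO selected no features at the chosen penalty")
    return block.subset(kept), coef


def select_chain(block: FeatureBlock, labels, alpha: float = 0.05,
                 r_threshold: float = 0.90, n_folds: int = 10,
                 seed: int = 0):
    """Run the full three-step chain; returns the selected block + audit.

    The audit dict carries the Mann-Whitney p-values, the columns surviving
    each stage and the LASSO coefficients.
    """
    mwu_block, ps = mwu_filter(block, labels, alpha=alpha)
    if mwu_block.n_features == 0:
        return mwu_block, {"mwu_p": ps, "after_mwu": [], "after_corr": [],
                           "lasso_coef": pd.Series(dtype=float)}
    corr_block = correlation_filter(mwu_block, r_threshold=r_threshold,
                                    order=ps)
    folds = min(n_folds, corr_block.n_subjects)
    sel_block, coef = lasso_select(corr_block, labels, n_folds=folds,
                                   seed=seed)
    audit = {
        "mwu_p": ps,
        "after_mwu": list(mwu_block.data.columns),
        "after_corr": list(corr_block.data.columns),
        "lasso_coef": coef,
    }
    return sel_block, audit
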