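"""Performance and clinical-utility evaluation.

Threshold metrics and AUC (rank statistic with midrank tie correction),
Brier score, DeLong's test for paired AUCs, decision-curve analysis, group
comparison tests, and a leakage-safe stratified k-fold cross-validation
orchestrator that refits all preprocessing, selection and models inside
every training fold.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ._types import EvalReport, FeatureBlock, NetBenefitCurve

__all__ = [
    "rank_auc",
    "binary_metrics",
    "delong_test",
    "decision_curve",
    "kfold_cv",
    "group_compare",
]


def _check_labels(labels):
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("labels must be binary with both classes present")
    return y


def rank_auc(probs, labels) -> float:
    """AUC via the Mann-Whitney rank statistic with midrank tie handling."""
    y = _check_labels(labels)
    p = np.asarray(probs, dtype=float)
    r = stats.rankdata(p)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def binary_metrics(probs, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion-matrix rates at a threshold, plus AUC and Brier score.

    The classification rule is ``prob >= threshold``. AUC comes from the
    rank statistic; Brier is the mean squared probability error.
    """
    y = _check_labels(labels)
    p = np.asarray(probs, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n1, n0 = tp + fn, tn + fp
    sens = tp / n1 if n1 else 0.0
    spec = tn / n0 if n0 else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens > 0 else 0.0
    return EvalReport(
        accuracy=(tp + tn) / len(y),
        auc=rank_auc(p, y),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f1=f1,
        brier=float(((p - y) ** 2).mean()),
        threshold=float(threshold),
        n_positive=n1,
        n_negative=n0,
    )


def youden_threshold(probs, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1."""
    y = _check_labels(labels)
    p = np.asarray(probs, dtype=float)
    cands = np.unique(p)
    best_t, best_j = 0.5, -np.inf
    for t in cands:
        pred = p >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def _placements(p, y):
    """DeLong placement values per class."""
    pos = p[y == 1]
    neg = p[y == 0]
    m, n = len(pos), len(neg)
    # V10[i] = fraction of negatives ranked below positive i (ties half).
    gt = pos[:, None] > neg[None, :]
    eq = pos[:, None] == neg[None, :]
    v10 = (gt.sum(axis=1) + 0.5 * eq.sum(axis=1)) / n
    v01 = (gt.sum(axis=0) + 0.5 * eq.sum(axis=0)) / m
    return v10, v01


def delong_test(probs_a, probs_b, labels):
    """DeLong's test for two correlated AUCs on paired predictions.

    Returns ``(auc_a, auc_b, z, p)``. Identical predictions give a
    degenerate variance; the comparison then reports z = 0, p = 1.
    """
    y = _check_labels(labels)
    pa = np.asarray(probs_a, dtype=float)
    pb = np.asarray(probs_b, dtype=float)
    if pa.shape != pb.shape or len(pa) != len(y):
        raise ValueError("paired predictions must align with labels")
    v10a, v01a = _placements(pa, y)
    v10b, v01b = _placements(pb, y)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def decision_curve(probs, labels, pt_grid=None) -> NetBenefitCurve:
    """Decision-curve analysis over a threshold-probability grid.

    Net benefit at threshold probability pt, for the rule ``prob >= pt``:

        NB(pt) = TP/n - (FP/n) * pt / (1 - pt)

    with treat-all and treat-none reference strategies included.
    """
    y = _check_labels(labels)
    p = np.asarray(probs, dtype=float)
    if pt_grid is None:
        pt_grid = np.arange(0.01, 0.801, 0.01)
    pt = np.asarray(pt_grid, dtype=float)
    if np.any(pt <= 0) or np.any(pt >= 1):
        raise ValueError("threshold probabilities must lie in (0, 1)")
    n = len(y)
    prev = y.mean()
    nb = np.empty_like(pt)
    for i, t in enumerate(pt):
        pred = p >= t
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[i] = tp - fp * t / (1.0 - t)
    treat_all = prev - (1.0 - prev) * pt / (1.0 - pt)
    return NetBenefitCurve(thresholds=pt, net_benefit=nb,
                           treat_all=treat_all,
                           treat_none=np.zeros_like(pt))


def kfold_cv(blocks, labels, fit_predict, k: int = 5, seed: int = 0,
             threshold: float = 0.5):
    """Stratified k-fold cross-validation with no leakage.

    ``fit_predict(train_blocks, train_labels, test_blocks) -> probs`` must
    encapsulate the entire pipeline (scaling, feature selection, model
    fitting); it is called once per fold on the training fold only, so any
    in-pipeline selection is refit fold-by-fold. Out-of-fold predictions
    are pooled and scored once.

    Returns ``(pooled_report, fold_reports, oof_probs)``.
    """
    y = _check_labels(labels)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError("k must lie in [2, n]")
    blocks = list(blocks)
    if k <= int(np.bincount(y).min()):
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        # stratification impossible (e.g. leave-one-out): plain K-fold
        from sklearn.model_selection import KFold

        cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(n, np.nan)
    fold_reports = []
    for tr, te in cv.split(np.zeros(n), y):
        tr_blocks = [FeatureBlock(b.data.iloc[tr], b.modality,
                                  dict(b.provenance)) for b in blocks]
        te_blocks = [FeatureBlock(b.data.iloc[te], b.modality,
                                  dict(b.provenance)) for b in blocks]
        probs = np.asarray(fit_predict(tr_blocks, y[tr], te_blocks),
                           dtype=float)
        oof[te] = probs
        if len(np.unique(y[te])) == 2:
            fold_reports.append(binary_metrics(probs, y[te], threshold))
    assert not np.isnan(oof).any()
    pooled = binary_metrics(oof, y, threshold)
    return pooled, fold_reports, oof


def group_compare(values, groups, kind: str = "auto") -> float:
    """Two-group comparison p-value.

    Continuous data: t-test (``kind='t'``) or Mann-Whitney U
    (``kind='mwu'``, the default under ``auto``). Categorical data
    (``kind='categorical'``): chi-square, falling back to Fisher's exact
    test when any expected cell count is below 5 (2x2 only).
    """
    v = np.asarray(values)
    g = np.asarray(groups)
    uniq = np.unique(g)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    a, b = v[g == uniq[0]], v[g == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if kind == "categorical":
        cats = np.unique(v)
        table = np.array([[(v[g == gr] == c).sum() for c in cats]
                          for gr in uniq])
        chi2, p, dof, expected = stats.chi2_contingency(table,
                                                        correction=False)
        if (expected < 5).any():
            if table.shape == (2, 2):
                return float(stats.fisher_exact(table)[1])
        return float(p)
    if kind == "t":
        return float(stats.ttest_ind(a, b).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
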