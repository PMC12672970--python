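"""Metrics, DeLong, decision curves, leakage-safe cross-validation."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habitatrisk._types import FeatureBlock
from habitatrisk.evaluation import (
    binary_metrics,
    decision_curve,
    delong_test,
    group_compare,
    kfold_cv,
    rank_auc,
    youden_threshold,
)


def _pairwise_auc(probs, labels):
    """Brute force over all positive-negative pairs."""
    p = np.asarray(probs)
    y = np.asarray(labels)
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_four_point_toy_auc(self):
        rep = binary_metrics([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert rep.auc == pytest.approx(0.75)

    def test_rank_auc_matches_pair_enumeration_and_trapezoid(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            n = 40
            y = rng.binomial(1, 0.5, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.random(n)           # tie-free almost surely
            ours = rank_auc(p, y)
            assert ours == pytest.approx(_pairwise_auc(p, y), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_perfect_and_uninformative_probabilities(self):
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        rep = binary_metrics(y.astype(float), y)
        assert rep.brier == 0.0
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
        flat = binary_metrics(np.full(20, 0.5), y)
        assert flat.brier == pytest.approx(0.25)

    def test_f1_consistent_with_ppv_and_sensitivity(self, rng):
        y = rng.binomial(1, 0.4, 100)
        p = np.clip(y * 0.6 + rng.random(100) * 0.4, 0, 1)
        rep = binary_metrics(p, y)
        if rep.ppv + rep.sensitivity > 0:
            f1 = 2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity)
            assert rep.f1 == pytest.approx(f1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([0.2, 0.4], [1, 1])

    def test_youden_threshold_maximizes_j(self, rng):
        y = rng.binomial(1, 0.5, 60)
        p = np.clip(0.5 * y + rng.random(60) * 0.5, 0, 1)
        t = youden_threshold(p, y)
        rep = binary_metrics(p, y, threshold=t)
        j_at_t = rep.sensitivity + rep.specificity - 1
        for cand in np.linspace(0.05, 0.95, 19):
            r = binary_metrics(p, y, threshold=cand)
            assert j_at_t >= r.sensitivity + r.specificity - 1 - 1e-12


class TestDeLong:
    def test_identical_predictions(self):
        p = [0.1, 0.4, 0.35, 0.8]
        a, b, z, pv = delong_test(p, p, [0, 0, 1, 1])
        assert a == b == pytest.approx(0.75)
        assert z == 0.0 and pv == 1.0

    def test_power_on_clearly_different_models(self, rng):
        n = 500
        y = rng.binomial(1, 0.5, n)
        strong = np.clip(y + rng.normal(0, 0.4, n), -2, 3)
        weak = np.clip(0.1 * y + rng.normal(0, 0.7, n), -2, 3)
        a, b, z, p = delong_test(strong, weak, y)
        assert a > 0.9 and b < 0.65
        assert p < 1e-6

    def test_variance_close_to_hanley_mcneil(self, rng):
        """On balanced tie-free data the DeLong SE is within 10% of the
        Hanley-McNeil binormal approximation."""
        n = 600
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        zs = []
        ses_hm = []
        for _ in range(30):
            p = np.clip(0.6 * y + rng.normal(0, 0.6, n), None, None)
            auc = rank_auc(p, y)
            # DeLong variance recovered from the paired test against an
            # uninformative independent score
            from habitatrisk.evaluation import _placements

            v10, v01 = _placements(p, y)
            var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
            q1 = auc / (2 - auc)
            q2 = 2 * auc ** 2 / (1 + auc)
            var_hm = (auc * (1 - auc) + (n / 2 - 1) * (q1 - auc ** 2)
                      + (n / 2 - 1) * (q2 - auc ** 2)) / (n / 2) ** 2
            zs.append(var)
            ses_hm.append(var_hm)
        assert np.mean(zs) == pytest.approx(np.mean(ses_hm), rel=0.10)


class TestDecisionCurve:
    def test_printed_toy_net_benefit(self):
        """TP = 30, FP = 10 at pt = 0.2 with n = 100 -> NB = 0.275."""
        probs = np.r_[np.full(30, 0.9), np.full(20, 0.05),
                      np.full(10, 0.9), np.full(40, 0.05)]
        labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
        curve = decision_curve(probs, labels, [0.2])
        assert curve.net_benefit[0] == pytest.approx(0.30 - 0.10 * 0.25)
        assert curve.treat_none[0] == 0.0

    def test_treat_none_zero_everywhere(self, rng):
        y = rng.binomial(1, 0.5, 50)
        curve = decision_curve(rng.random(50), y)
        assert np.all(curve.treat_none == 0.0)

    def test_net_benefit_bounded_by_prevalence(self, rng):
        y = rng.binomial(1, 0.4, 200)
        p = np.clip(0.5 * y + rng.random(200) * 0.5, 0, 1)
        curve = decision_curve(p, y)
        assert np.all(curve.net_benefit <= y.mean() + 1e-12)

    def test_perfect_model_attains_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)].astype(int)
        p = np.where(y == 1, 0.95, 0.02)
        curve = decision_curve(p, y, np.arange(0.05, 0.95, 0.05))
        below = curve.thresholds < 0.95
        assert np.allclose(curve.net_benefit[below], 0.30)

    def test_grid_bounds_enforced(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [0, 1], [1.0])


class TestKFoldCV:
    @staticmethod
    def _lr_fit_predict(select=False, leak_scores=None):
        from sklearn.linear_model import LogisticRegression

        def fp(tr_blocks, tr_y, te_blocks):
            xtr = tr_blocks[0].data
            xte = te_blocks[0].data
            if select:
                from habitatrisk.selection import mwu_pvalues

                ps = mwu_pvalues(tr_blocks[0], tr_y)
                cols = list(ps.nsmallest(5).index)
            elif leak_scores is not None:
                cols = list(leak_scores.nsmallest(5).index)
            else:
                cols = list(xtr.columns)
            m = LogisticRegression(max_iter=1000).fit(xtr[cols], tr_y)
            return m.predict_proba(xte[cols])[:, 1]
        return fp

    def test_fixed_seed_gives_identical_folds(self, rng):
        y = rng.binomial(1, 0.5, 60)
        x = FeatureBlock(pd.DataFrame(rng.standard_normal((60, 5)),
                                      columns=list("abcde")), "clinical")
        r1, _, oof1 = kfold_cv([x], y, self._lr_fit_predict(), k=5, seed=3)
        r2, _, oof2 = kfold_cv([x], y, self._lr_fit_predict(), k=5, seed=3)
        assert np.array_equal(oof1, oof2)

    def test_leave_one_out_boundary(self, rng):
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        x = FeatureBlock(pd.DataFrame(
            rng.standard_normal((20, 3)), columns=list("abc")), "clinical")
        pooled, folds, oof = kfold_cv([x], y, self._lr_fit_predict(), k=20,
                                      seed=0)
        assert len(oof) == 20
        assert np.isfinite(pooled.auc)

    def test_infold_selection_avoids_leakage_inflation(self, rng):
        """In-fold selection on pure noise stays near AUC 0.5; selecting on
        the full data before CV inflates it."""
        from habitatrisk.selection import mwu_pvalues

        n, p = 120, 200
        y = rng.binomial(1, 0.5, n)
        x = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"f{i}" for i in range(p)])
        block = FeatureBlock(x, "us_radiomic")
        clean, _, _ = kfold_cv([block], y, self._lr_fit_predict(select=True),
                               k=5, seed=0)
        full_ps = mwu_pvalues(block, y)
        leaky, _, _ = kfold_cv(
            [block], y, self._lr_fit_predict(leak_scores=full_ps),
            k=5, seed=0)
        assert abs(clean.auc - 0.5) < 0.1
        assert leaky.auc > clean.auc + 0.05


class TestGroupCompare:
    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[8, 2], [1, 9]])
        # enumeration oracle: sum of hypergeometric probabilities of
        # tables as or more extreme than observed
        n1, n2 = table[0].sum(), table[1].sum()
        k = table[:, 0].sum()
        obs = stats.hypergeom.pmf(table[0, 0], n1 + n2, k, n1)
        p_exact = sum(
            stats.hypergeom.pmf(a, n1 + n2, k, n1)
            for a in range(max(0, k - n2), min(k, n1) + 1)
            if stats.hypergeom.pmf(a, n1 + n2, k, n1) <= obs + 1e-12
        )
        values = np.r_[np.ones(8), np.zeros(2), np.ones(1), np.zeros(9)]
        groups = np.r_[np.zeros(10), np.ones(10)]
        p = group_compare(values, groups, kind="categorical")
        assert p == pytest.approx(p_exact, rel=1e-9)

    def test_identical_groups_p_one(self):
        v = np.r_[np.arange(10.0), np.arange(10.0)]
        g = np.r_[np.zeros(10), np.ones(10)]
        assert group_compare(v, g) == pytest.approx(1.0)

    def test_continuous_dispatch_and_errors(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 2.0
        v = np.r_[a, b]
        g = np.r_[np.zeros(30), np.ones(30)]
        assert group_compare(v, g, kind="t") < 1e-6
        assert group_compare(v, g) < 1e-6
        with pytest.raises(ValueError):
            group_compare(v, np.zeros(60))
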