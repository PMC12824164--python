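"""Evaluation suite against brute-force and library oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radpatho import evaluation


def pair_counting_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestDelong:
    def test_perfect_ranking(self):
        auc, var, ci = evaluation.auc_delong(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])
        )
        assert auc == 1.0
        assert ci[0] <= auc <= ci[1]

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = 30
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # ties likely
            auc, _, _ = evaluation.auc_delong(s, y)
            assert auc == pytest.approx(pair_counting_auc(s, y), abs=1e-12)

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        auc, _, _ = evaluation.auc_delong(s, y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            evaluation.auc_delong(np.array([0.1, 0.2]), np.array([1, 1]))


class TestPairedDelong:
    def test_identical_models_give_p_one(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        z, p = evaluation.delong_paired_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        y = np.tile([0, 1], 25)
        a, b = rng.random(50), rng.random(50)
        za, _ = evaluation.delong_paired_test(a, b, y)
        zb, _ = evaluation.delong_paired_test(b, a, y)
        assert za == pytest.approx(-zb)

    def test_agrees_with_bootstrap_difference(self, rng):
        n = 120
        y = np.tile([0, 1], n // 2)
        signal = rng.standard_normal(n)
        a = y + 0.8 * signal
        b = y + 1.6 * signal
        z, p = evaluation.delong_paired_test(a, b, y)
        # bootstrap the paired AUC difference
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            auc_a, _, _ = evaluation.auc_delong(a[idx], y[idx])
            auc_b, _, _ = evaluation.auc_delong(b[idx], y[idx])
            diffs.append(auc_a - auc_b)
        diffs = np.asarray(diffs)
        z_boot = diffs.mean() / diffs.std(ddof=1)
        assert z == pytest.approx(z_boot, rel=0.15)


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        m = evaluation.threshold_metrics(
            np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]), 0.5
        )
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"))

    def test_all_positive_calls(self):
        y = np.array([1, 1, 0, 0, 0])
        m = evaluation.threshold_metrics(np.ones(5), y, 0.5)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert m["ppv"] == pytest.approx(0.4)  # prevalence
        assert np.isnan(m["npv"])

    def test_hand_tabulated_ten_samples(self):
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.45, 0.4, 0.3, 0.2, 0.1])
        y = np.array([1, 1, 0, 1, 0, 1, 0, 0, 1, 0])
        m = evaluation.threshold_metrics(s, y, 0.5)
        # scores >= 0.5: first five → TP = 3 (idx 0,1,3), FP = 2 (idx 2,4)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 2, 2, 3)
        assert m["accuracy"] == pytest.approx(0.6)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["ppv"] == pytest.approx(0.6)

    def test_youden_picks_separating_cut(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        thr = evaluation.youden_threshold(s, y)
        m = evaluation.threshold_metrics(s, y, thr)
        assert m["sensitivity"] == m["specificity"] == 1.0


class TestCalibration:
    def test_constant_score_single_bin(self):
        with pytest.raises(ValueError):
            evaluation.calibration_curve(np.full(5, 0.3), np.zeros(5), n_bins=10)
        out = evaluation.calibration_curve(
            np.full(20, 0.3), np.tile([0, 1], 10), n_bins=10
        )
        assert len(out) == 1
        assert out["mean_predicted"].iloc[0] == pytest.approx(0.3)
        assert out["observed_rate"].iloc[0] == pytest.approx(0.5)

    def test_well_calibrated_scores_hug_diagonal(self, rng):
        p = rng.random(2000)
        y = (rng.random(2000) < p).astype(int)
        out = evaluation.calibration_curve(p, y, n_bins=10)
        assert (out["mean_predicted"] - out["observed_rate"]).abs().max() < 0.1


class TestDecisionCurve:
    def test_reference_policies(self):
        y = np.array([1, 1, 0, 0, 0])
        out = evaluation.decision_curve(np.ones(5) * 0.9, y, np.array([0.01, 0.5]))
        assert (out["treat_none"] == 0).all()
        # treat-all at t → 0 tends to prevalence
        assert out["treat_all"].iloc[0] == pytest.approx(0.4 - 0.6 * (0.01 / 0.99))

    def test_direct_formula_toy(self):
        # n=10, at t=0.5: TP=3, FP=1 → NB = 0.3 − 0.1·1 = 0.2
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1])
        out = evaluation.decision_curve(s, y, np.array([0.5]))
        assert out["net_benefit"].iloc[0] == pytest.approx(0.2)

    def test_invalid_thresholds_excluded(self):
        y = np.array([1, 0, 1, 0])
        out = evaluation.decision_curve(np.ones(4), y, np.array([0.5, 1.0, 1.5]))
        assert (out["threshold"] < 1).all() and len(out) == 1


class TestMcNemarAndMatching:
    def test_exact_binomial_arithmetic(self):
        assert evaluation.mcnemar_exact(1, 5) == pytest.approx(14 / 64)
        assert evaluation.mcnemar_exact(0, 0) == 1.0
        assert evaluation.mcnemar_exact(3, 3) <= 1.0

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(1, 5), (2, 9), (0, 4), (5, 5)]:
            table = [[10, b], [c, 10]]
            expect = sm_mcnemar(table, exact=True).pvalue
            assert evaluation.mcnemar_exact(b, c) == pytest.approx(expect)

    def test_swapping_raters_leaves_p_invariant(self):
        assert evaluation.mcnemar_exact(2, 7) == evaluation.mcnemar_exact(7, 2)

    def test_model_identical_to_rater(self):
        y = np.tile([0, 1], 20)
        calls = y.copy()
        out = evaluation.operating_point_match(calls.astype(float), y, calls)
        assert out["matchable"]
        assert out["delta_specificity"] == 0.0
        assert out["mcnemar_p"] == 1.0

    def test_matching_at_full_sensitivity_uses_lowest_threshold(self, rng):
        y = np.tile([0, 1], 25)
        s = rng.random(50) * 0.5 + y * 0.3
        calls = np.ones(50, dtype=int)  # rater calls everything positive
        out = evaluation.operating_point_match(s, y, calls, match="sensitivity")
        assert out["model"]["sensitivity"] == 1.0
        assert out["threshold"] <= s[y == 1].min()


class TestKappa:
    def test_identical_raters(self):
        k, band = evaluation.cohen_kappa([0, 1, 1, 0], [0, 1, 1, 0])
        assert k == 1.0 and band == "almost perfect"

    def test_hand_arithmetic_2x2(self):
        a = np.repeat([1, 1, 0, 0], [20, 5, 5, 30])
        b = np.repeat([1, 0, 1, 0], [20, 5, 5, 30])
        k, band = evaluation.cohen_kappa(a, b)
        assert k == pytest.approx(0.657, abs=1e-3)
        assert band == "substantial"

    def test_independent_raters_near_zero(self, rng):
        a = rng.integers(0, 2, 5000)
        b = rng.integers(0, 2, 5000)
        k, _ = evaluation.cohen_kappa(a, b)
        assert abs(k) < 0.05

    def test_symmetry(self, rng):
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        assert evaluation.cohen_kappa(a, b)[0] == pytest.approx(
            evaluation.cohen_kappa(b, a)[0]
        )

    def test_band_edges_closed_above(self):
        assert evaluation.kappa_band(0.80) == "substantial"
        assert evaluation.kappa_band(0.81) == "almost perfect"
        assert evaluation.kappa_band(0.20) == "poor"


class TestIcc:
    def test_identical_raters_give_one(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert evaluation.icc_agreement(X) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        X = rng.standard_normal((500, 3))
        assert abs(evaluation.icc_agreement(X)) < 0.1

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        items, raters = 25, 4
        X = rng.standard_normal((items, raters)) + rng.standard_normal(items)[:, None]
        df = pd.DataFrame(
            {
                "item": np.repeat(np.arange(items), raters),
                "rater": np.tile(np.arange(raters), items),
                "score": X.ravel(),
            }
        )
        icc_tab = pingouin.intraclass_corr(df, "item", "rater", "score")
        expect = icc_tab.loc[
            icc_tab["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"
        ].iloc[0]
        assert evaluation.icc_agreement(X) == pytest.approx(expect, abs=1e-10)

    def test_rater_offset_lowers_absolute_agreement(self, rng):
        base = rng.standard_normal(50)
        X = np.column_stack([base, base + 2.0])
        assert evaluation.icc_agreement(X) < 0.9
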