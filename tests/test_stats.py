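import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctdem import (
    ConfusionMatrix,
    auc_mann_whitney,
    compare_contingency,
    compare_groups,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    metrics_from_confusion,
    probability_from_feature,
    reconstruct_confusion,
    select_features,
    youden_threshold,
)

# Table 3 of the study: (sensitivity, specificity) with cohort 133 pos / 282 neg,
# and the printed accuracy / NPV / PPV / F1 each row implies.
TABLE3_ROWS = {
    "entropy": dict(se=0.895, sp=0.709, acc=0.769, npv=0.935, ppv=0.592, f1=0.713),
    "best_fd": dict(se=0.737, sp=0.667, acc=0.689, npv=0.843, ppv=0.510, f1=0.603),
    "max_fd": dict(se=0.797, sp=0.543, acc=0.624, npv=0.850, ppv=0.451, f1=0.576),
    "average_fd": dict(se=0.789, sp=0.546, acc=0.624, npv=0.846, ppv=0.451, f1=0.574),
    "median_fd": dict(se=0.774, sp=0.557, acc=0.627, npv=0.840, ppv=0.452, f1=0.571),
}
N_POS, N_NEG = 133, 282


class TestCompareGroups:
    def test_identical_multisets_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        res = compare_groups(x, x.copy())
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_degenerate_constant_flagged(self):
        res = compare_groups(np.full(10, 2.0), np.full(8, 2.0))
        assert res.degenerate and res.p_value == 1.0

    def test_routes_to_t_test_for_normal_homoscedastic(self, rng):
        res = compare_groups(rng.normal(0, 1, 80), rng.normal(0.5, 1, 80))
        assert res.test_name == "t-test"

    def test_routes_to_mwu_for_skewed(self, rng):
        res = compare_groups(rng.exponential(1, 80), rng.exponential(2, 80))
        assert res.test_name == "mann-whitney"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([]), np.array([1.0]))


class TestContingency:
    def test_gender_table_yates(self):
        res = compare_contingency([[229, 101], [53, 32]])
        assert res.test_name == "chi-square-yates"
        assert res.p_value == pytest.approx(0.267, abs=0.001)

    def test_location_table_df2(self):
        res = compare_contingency([[12, 10], [187, 90], [83, 33]])
        assert res.summaries["df"] == 2
        assert res.p_value == pytest.approx(0.282, abs=0.001)

    def test_fisher_for_small_2x2(self):
        res = compare_contingency([[2, 3], [8, 1]])
        assert res.test_name == "fisher-exact"
        expected = sps.fisher_exact([[2, 3], [8, 1]]).pvalue
        assert res.p_value == pytest.approx(expected)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_tied(self):
        assert auc_mann_whitney([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_enumerated_pairs(self):
        # pos {3,5}, neg {1,4}: 3 of 4 pairs concordant
        assert auc_mann_whitney([3, 5, 1, 4], [1, 1, 0, 0]) == 0.75

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 20)
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            oracle = wins / (len(pos) * len(neg))
            assert auc_mann_whitney(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_orientation_flip(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(-scores, labels)
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2], [1, 1])


class TestYouden:
    def test_separated_classes(self):
        r = youden_threshold([1, 2, 8, 9], [0, 0, 1, 1])
        assert 2 < r.threshold < 8
        assert r.metrics["sensitivity"] == 1.0 and r.metrics["specificity"] == 1.0

    def test_scores_equal_labels(self):
        r = youden_threshold([0, 0, 1, 1], [0, 0, 1, 1])
        assert 0 < r.threshold < 1
        assert r.metrics["accuracy"] == 1.0

    def test_tie_break_to_lower_threshold(self):
        # pos {3,5}, neg {1,4}: J = 0.5 at cuts 2.0 and 4.5 -> pick 2.0
        r = youden_threshold([3, 5, 1, 4], [1, 1, 0, 0])
        assert r.threshold == pytest.approx(2.0)

    def test_confusion_counts_consistent(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        r = youden_threshold(scores, labels)
        c = r.confusion
        assert c.tp + c.fn == labels.sum()
        assert c.tn + c.fp == (1 - labels).sum()


class TestConfusionMetrics:
    def test_balanced_flips_half_accuracy(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=10, fp=10, fn=10, tn=10))
        assert m["accuracy"] == 0.5

    def test_zero_denominator_is_nan(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert np.isnan(m["ppv"])

    @pytest.mark.parametrize("row", list(TABLE3_ROWS))
    def test_reconstruction_reproduces_printed_metrics(self, row):
        vals = TABLE3_ROWS[row]
        cm = reconstruct_confusion(vals["se"], vals["sp"], N_POS, N_NEG)
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(vals["acc"], abs=0.001)
        assert m["ppv"] == pytest.approx(vals["ppv"], abs=0.001)
        assert m["npv"] == pytest.approx(vals["npv"], abs=0.001)
        assert m["f1"] == pytest.approx(vals["f1"], abs=0.001)

    def test_reconstruct_counts(self):
        cm = reconstruct_confusion(0.895, 0.709, N_POS, N_NEG)
        assert (cm.tp, cm.tn) == (119, 200)
        cm = reconstruct_confusion(0.737, 0.667, N_POS, N_NEG)
        assert (cm.tp, cm.tn) == (98, 188)
        cm = reconstruct_confusion(1.0, 1.0, 10, 20)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 0, 0, 20)


class TestSelectFeatures:
    def test_label_plus_noise_retained_and_pure_noise_removed(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        table = pd.DataFrame(
            {
                "label": y,
                "good": y + rng.normal(0, 0.1, n),
                "noise": rng.normal(0, 1, n),
            }
        )
        retained, details = select_features(table)
        assert "good" in retained
        assert "noise" not in retained
        assert details.loc["good", "retained"]

    def test_significant_but_weak_auc_removed(self, rng):
        # large n makes a small shift significant while AUC stays ~0.56
        n = 4000
        y = np.repeat([0, 1], n // 2)
        x = np.where(y == 1, rng.normal(0.2, 1, n), rng.normal(0, 1, n))
        table = pd.DataFrame({"label": y, "weak": x})
        retained, details = select_features(table)
        assert details.loc["weak", "p_value"] < 0.05
        assert details.loc["weak", "auc_oriented"] < 0.7
        assert "weak" not in retained

    def test_negatively_oriented_feature_retained(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        table = pd.DataFrame({"label": y, "neg": -y + rng.normal(0, 0.1, n)})
        retained, details = select_features(table)
        assert "neg" in retained
        assert details.loc["neg", "orientation"] == -1


class TestDelong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        auc_a, auc_b, z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0 and auc_a == auc_b

    def test_strong_effect_detected(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        perfect = y.astype(float)
        noise = rng.normal(size=n)
        *_, p = delong_test(perfect, noise, y)
        assert p < 0.001

    def test_type_one_error_calibrated(self):
        # two independent-noise score vectors: p should be ~ Uniform(0, 1)
        rng = np.random.default_rng(1234)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            y = np.repeat([0, 1], 100)
            pa = delong_test(rng.normal(size=200), rng.normal(size=200), y)[3]
            rejections += pa < 0.05
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_symmetry(self, rng):
        y = rng.integers(0, 2, 80)
        a, b = rng.normal(size=80), rng.normal(size=80)
        _, _, z1, p1 = delong_test(a, b, y)
        _, _, z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_constructed(self):
        # within each risk bin the observed rate equals the predicted rate
        probs, labels = [], []
        for p, n in [(0.1, 40), (0.3, 40), (0.5, 40), (0.7, 40), (0.9, 40)]:
            k = int(round(p * n))
            probs += [p] * n
            labels += [1] * k + [0] * (n - k)
        res = hosmer_lemeshow(np.array(probs), np.array(labels), g=5)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_simulated_calibrated_probs_pass(self):
        # df = g-2 (the regression convention) is slightly anticonservative
        # when the probabilities are known-true, hence a fixed seed
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 1000)
        y = rng.binomial(1, p)
        res = hosmer_lemeshow(p, y, g=10)
        assert res.p_value > 0.05

    def test_anticalibrated_fails(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        p = np.clip(1.0 - y + rng.normal(0, 0.01, 200), 0.001, 0.999)
        res = hosmer_lemeshow(p, y)
        assert res.p_value < 0.001

    def test_bins_partition_sample(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 300)
        y = rng.integers(0, 2, 300)
        res = hosmer_lemeshow(p, y, g=10)
        assert sum(n for _, _, n in res.bins) == 300

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5, 1.2], [0, 1])


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        c = decision_curve(rng.uniform(0, 1, 50), rng.integers(0, 2, 50))
        assert np.all(c.treat_none == 0.0)

    def test_treat_all_closed_form(self):
        y = np.array([1] * 133 + [0] * 282)
        p = np.linspace(0, 1, 415)
        c = decision_curve(p, y, thresholds=[0.2])
        prev = 133 / 415
        assert c.treat_all[0] == pytest.approx(prev - (282 / 415) * 0.25, abs=1e-12)
        assert c.treat_all[0] == pytest.approx(0.1506, abs=0.0001)

    def test_treat_all_matches_closed_form_everywhere(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.uniform(0, 1, 200)
        c = decision_curve(p, y)
        prev = y.mean()
        expected = prev - (1 - prev) * c.thresholds / (1 - c.thresholds)
        np.testing.assert_allclose(c.treat_all, expected, atol=1e-12)

    def test_perfect_probs_net_benefit_is_prevalence(self):
        y = np.array([0, 0, 0, 1, 1])
        c = decision_curve(y.astype(float), y, thresholds=np.arange(0.05, 1.0, 0.05))
        np.testing.assert_allclose(c.model, y.mean(), atol=1e-12)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[1.0])


class TestProbabilityLink:
    def test_feature_equal_label(self):
        y = np.array([0] * 20 + [1] * 20)
        probs, info = probability_from_feature(y.astype(float), y)
        assert info["separation"]
        assert np.all(probs[y == 1] > 0.9) and np.all(probs[y == 0] < 0.1)

    def test_independent_feature_gives_prevalence(self, rng):
        y = np.array([0] * 150 + [1] * 50)
        x = rng.normal(size=200)
        probs, info = probability_from_feature(x, y)
        assert not info["separation"]
        np.testing.assert_allclose(probs.mean(), 0.25, atol=0.02)
        assert probs.std() < 0.1

    def test_monotone_calibration_for_informative_feature(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        x = y + rng.normal(0, 1.0, n)  # AUC ~ 0.76
        probs, _ = probability_from_feature(x, y)
        order = np.argsort(x)
        assert np.all(np.diff(probs[order]) >= -1e-12)
        res = hosmer_lemeshow(probs, y)
        assert res.p_value > 0.01
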