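"""Evaluation harness: splits, logistic regression, ROC/accuracy oracles,
Mann-Whitney tests, and the repeated-resampling study driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import modemdwi as m
from modemdwi.evaluation import _mw_exact, _u_stat


def brute_force_auc(labels, scores):
    """All-pairs oracle: P(score_pos > score_neg) + 1/2 P(tie)."""
    labels = np.asarray(labels, bool)
    pos = np.asarray(scores, float)[labels]
    neg = np.asarray(scores, float)[~labels]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestSplit:
    def test_80_20_disjoint_exhaustive(self):
        labels = np.repeat([0, 1], 50)
        tr, te = m.split_80_20(100, labels, seed=1)
        assert len(tr) == 80 and len(te) == 20
        assert len(np.intersect1d(tr, te)) == 0
        assert np.array_equal(np.union1d(tr, te), np.arange(100))

    def test_stratification_on_tiny_set(self):
        # 10 samples, 5 per class: every split keeps 1 test sample per class
        labels = np.repeat([0, 1], 5)
        for seed in range(10):
            _, te = m.split_80_20(10, labels, seed=seed)
            assert sorted(labels[te]) == [0, 1]

    def test_determinism_and_small_class_error(self):
        labels = np.repeat([0, 1], 50)
        a = m.split_80_20(100, labels, seed=7)
        b = m.split_80_20(100, labels, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        with pytest.raises(ValueError, match=">= 5"):
            m.split_80_20(6, np.array([0, 0, 0, 1, 1, 1]))


class TestROC:
    def test_worked_example(self):
        # pos {0.9, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs ordered -> 0.75
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.4, 0.6, 0.2]
        assert m.roc_auc(labels, scores) == 0.75

    def test_perfect_and_reversed(self):
        labels = [0, 0, 1, 1]
        assert m.roc_auc(labels, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert m.roc_auc(labels, [0.9, 0.8, 0.2, 0.1]) == 0.0
        scores = [0.3, 0.6, 0.5, 0.9]
        assert m.roc_auc(labels, [-s for s in scores]) == \
            pytest.approx(1.0 - m.roc_auc(labels, scores))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            m.roc_auc([1, 1], [0.2, 0.3])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle_with_ties(self, data):
        """Rank-based AUC equals the all-pairs statistic on every random
        instance with n <= 50, including heavy ties."""
        n = data.draw(st.integers(4, 50))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n,
                                    max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        # coarse grid of scores forces ties
        scores = data.draw(st.lists(st.integers(0, 5), min_size=n,
                                    max_size=n))
        assert m.roc_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12)

    def test_accuracy_at_half_threshold(self):
        labels = [0, 1, 1, 0]
        scores = [0.2, 0.9, 0.4, 0.6]
        assert m.accuracy(labels, scores) == 0.5
        assert m.accuracy(labels, scores, threshold=0.35) == 0.75


class TestLogistic:
    def test_perfect_separation_gives_auc_one(self):
        rng = np.random.default_rng(0)
        x_tr = np.vstack([rng.normal(0, 0.1, (30, 1)),
                          rng.normal(3, 0.1, (30, 1))])
        y_tr = np.repeat([0, 1], 30)
        x_te = np.array([[0.1], [2.9], [0.0], [3.1]])
        proba, beta, sds = m.logistic_on_params(x_tr, y_tr, x_te)
        assert m.roc_auc([0, 1, 0, 1], proba) == 1.0
        assert beta.shape == (1,)
        assert np.all(np.isfinite(proba))

    def test_label_permutation_null(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(400, 3))
        y = rng.integers(0, 2, size=400)
        tr, te = m.split_80_20(400, y, seed=0)
        proba, _, _ = m.logistic_on_params(x[tr], y[tr], x[te])
        assert 0.35 < m.roc_auc(y[te], proba) < 0.65


class TestCoefficientNormalization:
    def test_single_feature_gets_weight_one(self):
        w = m.normalize_coefficients(np.array([-2.3]), np.array([0.4]))
        assert w == pytest.approx([1.0])

    def test_scaled_magnitudes(self):
        w = m.normalize_coefficients(np.array([0.3, -0.1]),
                                     np.array([1.0, 1.0]))
        assert w == pytest.approx([0.75, 0.25])
        assert w.sum() == pytest.approx(1.0)

    def test_invariance_to_feature_rescaling(self):
        # feature x10 -> beta /10, SD x10 -> weights unchanged
        beta = np.array([0.5, -1.5, 0.2])
        sds = np.array([2.0, 0.3, 5.0])
        w1 = m.normalize_coefficients(beta, sds)
        scale = np.array([10.0, 1.0, 0.1])
        w2 = m.normalize_coefficients(beta / scale, sds * scale)
        assert np.allclose(w1, w2)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            m.normalize_coefficients(np.zeros(3), np.ones(3))


class TestMannWhitney:
    def test_exact_enumeration_toy(self):
        # {1,2} vs {3,4}: 2 of the 6 assignments are as extreme -> p = 1/3
        assert m.mann_whitney_compare([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            assert m.mann_whitney_compare([2, 2, 2], [2, 2]) == 1.0
        assert m.mann_whitney_compare([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_vs_asymptotic_agree_at_n8(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.8, 1.0, 8)
        from scipy.stats import mannwhitneyu
        p_exact = _mw_exact(a, b)
        p_asym = mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.02

    def test_u_statistic_with_ties(self):
        assert _u_stat(np.array([1.0, 2.0]), np.array([2.0, 0.0])) == 2.5

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            m.mann_whitney_compare([1.0], [2.0, 3.0])


class TestRunStudy:
    @pytest.fixture(scope="class")
    def small_report(self, cellsize_table, protocol13):
        return m.run_study(cellsize_table, methods=("modem", "mono", "dki"),
                           protocol=protocol13, n_iterations=3,
                           master_seed=17,
                           mlp_overrides={"batch_size": 32,
                                          "learning_rate": 1e-2,
                                          "early_stop_patience": 20})

    def test_record_counts(self, small_report):
        rec = small_report.records
        assert len(rec) == 3 * 3  # methods x iterations
        assert set(rec.method) == {"modem", "mono", "dki"}
        assert rec.groupby("method").size().nunique() == 1
        assert np.all((rec.auc >= 0) & (rec.auc <= 1))
        assert np.all((rec.accuracy >= 0) & (rec.accuracy <= 1))

    def test_normalized_coefficients_sum_to_one(self, small_report):
        for model, frame in small_report.coefficients.items():
            assert frame["normalized_coefficient"].sum() == \
                pytest.approx(1.0)
            assert np.all(frame["normalized_coefficient"] >= 0)

    def test_determinism(self, cellsize_table, protocol13):
        kwargs = dict(methods=("mono",), protocol=protocol13,
                      n_iterations=2, master_seed=4)
        r1 = m.run_study(cellsize_table, **kwargs)
        r2 = m.run_study(cellsize_table, **kwargs)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_shuffled_labels_are_chance_level(self, cellsize_table,
                                              protocol13):
        rng = np.random.default_rng(8)
        shuffled = cellsize_table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        rep = m.run_study(shuffled, methods=("mono",), protocol=protocol13,
                          n_iterations=20, master_seed=2)
        mean_auc = rep.records.auc.mean()
        assert 0.45 < mean_auc < 0.55


class TestProbabilityExport:
    def test_table_shape_and_identity(self):
        coords = pd.DataFrame({"x": [1, 2, 3], "y": [4, 5, 6],
                               "slice": [0, 0, 1]})
        proba = np.array([0.1, 0.8, 0.5])
        out = m.probability_map_export(proba, coords)
        assert len(out) == 3
        assert np.all((out.probability >= 0) & (out.probability <= 1))
        assert out.probability.mean() == pytest.approx(proba.mean())
        with pytest.raises(ValueError, match="length"):
            m.probability_map_export(proba[:2], coords)
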