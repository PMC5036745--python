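"""AUC, DeLong, repeated CV, subset models, learning curves and rankings."""

import numpy as np
import pandas as pd
import pytest

from macepredict.evaluation import (AUCSummary, ClassifierSpec, CVProtocol, MixedNB,
                                    auc, cv_auc_summary, delong_test,
                                    feature_subset_models, learning_curve,
                                    make_classifier, rank_risk_factors, run_cv,
                                    summarize_auc)


def brute_force_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_and_null(self):
        assert auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert auc([2, 2, 2, 2], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_matches_pairwise_enumeration_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert abs(auc(scores, labels) - brute_force_auc(scores, labels)) <= 1e-12


class TestSummarize:
    def test_identical_values_zero_width_ci(self):
        s = summarize_auc([0.7, 0.7, 0.7])
        assert s.mean == pytest.approx(0.7)
        assert s.ci[1] - s.ci[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_t_interval(self):
        s = summarize_auc([0.70, 0.71, 0.72, 0.73, 0.74])
        assert s.mean == pytest.approx(0.72)
        # sd=0.0158114, sem=0.0070711, t_{.975,4}=2.776445 -> half-width 0.0196334
        assert s.ci[0] == pytest.approx(0.7003666, abs=1e-6)
        assert s.ci[1] == pytest.approx(0.7396334, abs=1e-6)
        assert s.ci[0] <= s.mean <= s.ci[1]

    def test_permutation_invariance(self):
        a = summarize_auc([0.70, 0.74, 0.72])
        b = summarize_auc([0.72, 0.70, 0.74])
        assert a == b

    def test_fewer_than_two_reps_rejected(self):
        with pytest.raises(ValueError):
            summarize_auc([0.7])


class TestDeLong:
    def test_identical_curves_give_zero_z_unit_p(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        r = delong_test(s, s, y)
        assert r.diff == 0.0 and r.z == 0.0 and r.p_value == 1.0

    def test_swapping_scores_negates_difference_preserves_p(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 30)
        a = rng.normal(size=60) + y
        b = rng.normal(size=60) + 0.3 * y
        r1 = delong_test(a, b, y)
        r2 = delong_test(b, a, y)
        assert r1.diff == pytest.approx(-r2.diff)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert 0 <= r1.p_value <= 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [1, 2, 3], [0, 1])

    def test_variance_agrees_with_paired_bootstrap(self):
        """DeLong's structural-component variance of the AUC difference
        tracks a paired nonparametric bootstrap on a 50-case fixture."""
        rng = np.random.default_rng(7)
        n = 50
        y = np.array([0] * 30 + [1] * 20)
        a = rng.normal(size=n) + 1.1 * y
        b = rng.normal(size=n) + 0.6 * y
        res = delong_test(a, b, y)
        boot = []
        for _ in range(10_000):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            boot.append(auc(a[idx], yb) - auc(b[idx], yb))
        boot_var = float(np.var(boot, ddof=1))
        assert res.variance == pytest.approx(boot_var, rel=0.15)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(3)
    n, p = 120, 6
    X = rng.normal(size=(n, p))
    eta = 1.5 * X[:, 0] - 1.0 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y


class TestRunCV:
    def test_protocol_shape_and_determinism(self, toy_data):
        X, y = toy_data
        proto = CVProtocol(folds=5, repetitions=3, base_seed=9)
        s1 = run_cv(X, y, ClassifierSpec("nb"), proto)
        s2 = run_cv(X, y, ClassifierSpec("nb"), proto)
        assert s1.shape == (3, len(y))
        assert np.array_equal(s1, s2)
        assert not np.array_equal(s1[0], s1[1])  # folds differ across reps

    def test_separable_data_near_perfect_lasso(self):
        rng = np.random.default_rng(5)
        n = 100
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({"sep": y + 0.01 * rng.normal(size=n),
                          "noise": rng.normal(size=n)})
        s = run_cv(X, y, ClassifierSpec("l1lr"), CVProtocol(repetitions=2))
        assert cv_auc_summary(s, y).mean >= 0.99

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("boosting")


class TestMixedNB:
    def test_probabilities_normalize_and_discriminate(self):
        rng = np.random.default_rng(11)
        n = 300
        y = rng.integers(0, 2, size=n)
        X = np.column_stack([
            y + rng.normal(scale=0.6, size=n),          # numeric signal
            (rng.random(n) < 0.2 + 0.5 * y).astype(float),  # binary signal
        ])
        m = MixedNB().fit(X, y)
        proba = m.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert auc(proba[:, 1], y) > 0.8
        assert m.binary_cols_.tolist() == [False, True]


class TestSubsetAndCurve:
    def test_full_subset_reproduces_run_cv(self, toy_data):
        X, y = toy_data
        proto = CVProtocol(repetitions=2, base_seed=4)
        full = cv_auc_summary(run_cv(X, y, ClassifierSpec("nb"), proto), y)
        sub = feature_subset_models(X, y, list(X.columns), [ClassifierSpec("nb")], proto)
        assert sub["nb"] == full

    def test_uninformative_single_column_near_half(self):
        rng = np.random.default_rng(21)
        n = 600
        X = pd.DataFrame({"noise": rng.normal(size=n)})
        y = np.array([0, 1] * (n // 2))
        proto = CVProtocol(repetitions=3, base_seed=4)
        sub = feature_subset_models(X, y, ["noise"], [ClassifierSpec("nb")], proto)
        assert abs(sub["nb"].mean - 0.5) < 0.1

    def test_empty_subset_rejected(self, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError):
            feature_subset_models(X, y, [], [ClassifierSpec("nb")])

    def test_learning_curve_full_fraction_equals_run_cv(self, toy_data):
        X, y = toy_data
        proto = CVProtocol(repetitions=2, base_seed=4)
        curve = learning_curve(X, y, [1.0], [ClassifierSpec("nb")], proto)
        full = cv_auc_summary(run_cv(X, y, ClassifierSpec("nb"), proto), y)
        assert curve["nb"][1.0] == full

    def test_learning_curve_rejects_bad_fraction(self, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError):
            learning_curve(X, y, [1.5], [ClassifierSpec("nb")])
        with pytest.raises(ValueError):
            learning_curve(X, y, [0.05], [ClassifierSpec("nb")])


class TestRanking:
    def test_planted_factor_ranked_first_by_both_paths(self, toy_data):
        X, y = toy_data
        rf_rank = rank_risk_factors("rf", X, y, seed=0, n_repeats=3)
        lr_rank = rank_risk_factors("l1lr", X, y, seed=0)
        assert rf_rank[0][0] in ("f0", "f1")
        assert lr_rank[0][0] == "f0" and lr_rank[0][1] > 0

    def test_lasso_sign_tracks_effect_direction(self, toy_data):
        X, y = toy_data
        coef = dict(rank_risk_factors("l1lr", X, y, seed=0))
        assert coef["f0"] > 0 and coef["f1"] < 0

    def test_constant_column_has_zero_permutation_importance(self, toy_data):
        X, y = toy_data
        X = X.copy()
        X["const"] = 1.0
        imp = dict(rank_risk_factors("rf", X, y, seed=0, n_repeats=2, top_k=10))
        assert imp["const"] == 0.0

    def test_unknown_ranking_kind_rejected(self, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError):
            rank_risk_factors("svm", X, y)
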