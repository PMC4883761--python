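"""Risk models: recovery, nesting, Bayes oracle, SVM behaviour, round trips."""

import numpy as np
import pandas as pd
import pytest

import postoprisk as pk
from postoprisk.models import (
    GamModel,
    LogisticModel,
    NaiveBayesModel,
    logistic_standard_errors,
)


@pytest.fixture(scope="module")
def linear_truth():
    """Well-specified logistic cohort for coefficient recovery."""
    cohort, tm = pk.make_gaussian_cohort(
        12_000,
        linear={"x1": 0.8, "x2": -0.5, "x3": 0.3},
        binary={"b1": (0.2, 0.6)},
        prevalence=0.36,
        seed=21,
    )
    return cohort, tm


class TestLogistic:
    def test_coefficient_recovery_within_3se(self, linear_truth):
        cohort, tm = linear_truth
        y = cohort.outcomes["y"].to_numpy()
        model = pk.fit_logistic(cohort.X, y)
        se = logistic_standard_errors(cohort.X, y)
        truth = {"x1": 0.8, "x2": -0.5, "x3": 0.3, "b1": 0.6}
        for i, f in enumerate(model.feature_names):
            assert abs(model.params[i + 1] - truth[f]) < 3 * se[i + 1], f
        assert abs(model.params[0] - tm.outcomes["y"].intercept) < 3 * se[0]

    def test_null_intercept_is_logit_prevalence(self):
        from scipy.special import logit

        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=5000)})
        y = rng.binomial(1, 0.3, 5000)
        model = pk.fit_logistic(X, y)
        assert model.params[0] == pytest.approx(logit(y.mean()), abs=0.1)

    def test_risks_in_unit_interval_mean_matches_prevalence(self, linear_truth):
        cohort, _ = linear_truth
        y = cohort.outcomes["y"].to_numpy()
        model = pk.fit_logistic(cohort.X, y)
        p = model.predict_risk(cohort.X)
        assert np.all((p > 0) & (p < 1))
        # MLE score equation: fitted mean equals observed prevalence
        assert p.mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_serialization_roundtrip_exact(self, linear_truth):
        cohort, _ = linear_truth
        y = cohort.outcomes["y"].to_numpy()
        model = pk.fit_logistic(cohort.X, y)
        back = LogisticModel.from_dict(model.to_dict())
        assert np.allclose(
            back.predict_risk(cohort.X), model.predict_risk(cohort.X), atol=1e-12
        )

    def test_schema_mismatch_rejected(self, linear_truth):
        cohort, _ = linear_truth
        model = pk.fit_logistic(cohort.X, cohort.outcomes["y"].to_numpy())
        with pytest.raises(ValueError):
            model.predict_risk(cohort.X[["x1"]])

    def test_permutation_equivariance(self, linear_truth):
        cohort, _ = linear_truth
        model = pk.fit_logistic(cohort.X, cohort.outcomes["y"].to_numpy())
        perm = np.random.default_rng(1).permutation(cohort.n)
        p = model.predict_risk(cohort.X)
        assert np.allclose(model.predict_risk(cohort.X.iloc[perm]), p[perm])


class TestGam:
    @pytest.fixture(scope="class")
    def ushape_truth(self):
        cohort, tm = pk.make_gaussian_cohort(
            12_000,
            linear={"xl": 0.8, "xl2": -0.5},
            quadratic={"xq": (1.0, 0.0)},
            prevalence=0.36,
            seed=22,
        )
        y = cohort.outcomes["y"].to_numpy()
        model, diag = pk.fit_gam(
            cohort.X, y, smooth_features=["xq", "xl"], search="refine"
        )
        return cohort, tm, model, diag

    def test_linear_term_linearized(self, ushape_truth):
        _, _, model, diag = ushape_truth
        assert "xl" in diag.linearized
        assert diag.edf["xl"] < 1.5
        assert "xl" in model.linear_features

    def test_ushape_recovered(self, ushape_truth):
        _, _, model, diag = ushape_truth
        assert diag.edf["xq"] > 2
        grid = np.linspace(-2.5, 2.5, 60)
        eff = model.partial_effect("xq", grid)
        truth = grid**2 - 1
        r = np.corrcoef(eff, truth)[0, 1]
        assert r > 0.95
        # non-monotone with interior argmin near zero
        assert abs(grid[np.argmin(eff)]) < 0.5

    def test_linear_slope_recovered(self, ushape_truth):
        cohort, _, model, _ = ushape_truth
        y = cohort.outcomes["y"].to_numpy()
        se = logistic_standard_errors(cohort.X, y)  # conservative scale reference
        beta = model.params[1 + model.linear_features.index("xl")]
        assert abs(beta - 0.8) < 4 * se[1 + list(cohort.X.columns).index("xl")]

    def test_all_linear_nests_logistic(self, linear_truth):
        cohort, _ = linear_truth
        y = cohort.outcomes["y"].to_numpy()
        gam, _ = pk.fit_gam(cohort.X, y, smooth_features=[])
        lr = pk.fit_logistic(cohort.X, y)
        assert np.allclose(
            gam.predict_risk(cohort.X), lr.predict_risk(cohort.X), atol=1e-6
        )

    def test_few_distinct_values_demoted(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"d": rng.integers(0, 4, 2000).astype(float), "x": rng.normal(size=2000)}
        )
        y = rng.binomial(1, 0.4, 2000)
        with pytest.warns(UserWarning):
            model, diag = pk.fit_gam(X, y, smooth_features=["d", "x"])
        assert "d" in diag.linearized

    def test_serialization_roundtrip(self, ushape_truth):
        cohort, _, model, _ = ushape_truth
        back = GamModel.from_dict(model.to_dict())
        assert np.allclose(
            back.predict_risk(cohort.X), model.predict_risk(cohort.X), atol=1e-10
        )

    def test_prediction_clamps_outside_training_range(self, ushape_truth):
        cohort, _, model, _ = ushape_truth
        Xnew = cohort.X.head(5).copy()
        Xnew.loc[:, "xq"] = 1e6
        p = model.predict_risk(Xnew)
        assert np.all(np.isfinite(p))


class TestNaiveBayes:
    def test_exact_bayes_posterior_on_2x2_table(self):
        # brute-force oracle: single binary feature, full table known
        x = np.array([1.0] * 60 + [0.0] * 40 + [1.0] * 20 + [0.0] * 80)
        y = np.array([1] * 100 + [0] * 100)
        X = pd.DataFrame({"b": x})
        model = pk.fit_naive_bayes(X, y, categorical_features=["b"])
        p = model.predict_risk(pd.DataFrame({"b": [1.0, 0.0]}))
        # Laplace-smoothed conditionals, equal priors
        p1_given_x1 = (60 + 1) / (100 + 2)
        p1_given_x0 = (40 + 1) / (100 + 2)
        p0_given_x1 = (20 + 1) / (100 + 2)
        p0_given_x0 = (80 + 1) / (100 + 2)
        expected1 = p1_given_x1 / (p1_given_x1 + p0_given_x1)
        expected0 = p1_given_x0 / (p1_given_x0 + p0_given_x0)
        assert p[0] == pytest.approx(expected1, abs=1e-12)
        assert p[1] == pytest.approx(expected0, abs=1e-12)

    def test_independent_feature_posterior_half(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=20_000)})
        y = np.tile([0, 1], 10_000)
        model = pk.fit_naive_bayes(X, y)
        p = model.predict_risk(X.head(200))
        assert np.allclose(p, 0.5, atol=0.1)

    def test_posterior_is_normalized_probability(self, linear_truth):
        cohort, _ = linear_truth
        model = pk.fit_naive_bayes(cohort.X, cohort.outcomes["y"].to_numpy())
        p = model.predict_risk(cohort.X)
        assert np.all((p >= 0) & (p <= 1))

    def test_zero_variance_floored_with_warning(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(50), np.random.default_rng(5).normal(size=50)]})
        y = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        with pytest.warns(UserWarning):
            model = pk.fit_naive_bayes(X, y, categorical_features=[])
        assert np.all(np.isfinite(model.predict_risk(X)))

    def test_serialization_roundtrip(self, linear_truth):
        cohort, _ = linear_truth
        model = pk.fit_naive_bayes(cohort.X, cohort.outcomes["y"].to_numpy())
        back = NaiveBayesModel.from_dict(
            __import__("json").loads(__import__("json").dumps(model.to_dict()))
        )
        assert np.allclose(
            back.predict_risk(cohort.X), model.predict_risk(cohort.X), atol=1e-12
        )


class TestSvm:
    def test_separable_toy_set_perfect(self):
        X = pd.DataFrame(
            {"a": [0, 0, 1, 1, 4, 4, 5, 5.0], "b": [0, 1, 0, 1, 4, 5, 4, 5.0]}
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = pk.fit_svm(X, y, kernel="linear", class_weight=None)
        scores = model.predict_risk(X)
        assert np.all((scores > 0) == (y == 1))

    def test_auc_invariant_to_monotone_rescaling(self, linear_truth):
        cohort, _ = linear_truth
        y = cohort.outcomes["y"].to_numpy()
        sub = cohort.X.head(1500)
        model = pk.fit_svm(sub, y[:1500])
        s = model.predict_risk(sub)
        assert pk.auc(s, y[:1500]) == pytest.approx(pk.auc(3 * s + 7, y[:1500]))

    def test_linear_svm_tracks_logistic_on_logistic_data(self):
        diffs = []
        for seed in (0, 1, 2):
            cohort, _ = pk.make_gaussian_cohort(
                6000,
                linear={"x1": 0.9, "x2": -0.6, "x3": 0.4},
                prevalence=0.4,
                seed=seed,
            )
            y = cohort.outcomes["y"].to_numpy()
            tr, va = np.arange(0, 4000), np.arange(4000, 6000)
            lr = pk.fit_logistic(cohort.X.iloc[tr], y[tr])
            svm = pk.fit_svm(cohort.X.iloc[tr], y[tr], kernel="linear")
            a_lr = pk.auc(lr.predict_risk(cohort.X.iloc[va]), y[va])
            a_svm = pk.auc(svm.predict_risk(cohort.X.iloc[va]), y[va])
            diffs.append(abs(a_lr - a_svm))
        assert max(diffs) < 0.02

    def test_platt_probabilities_in_unit_interval(self):
        cohort, _ = pk.make_gaussian_cohort(800, linear={"x": 1.0}, seed=6)
        y = cohort.outcomes["y"].to_numpy()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = pk.fit_svm(cohort.X, y, platt=True)
        p = model.predict_risk(cohort.X)
        assert model.probabilistic
        assert np.all((p >= 0) & (p <= 1))

    def test_to_dict_carries_support_vectors(self, linear_truth):
        cohort, _ = linear_truth
        y = cohort.outcomes["y"].to_numpy()
        model = pk.fit_svm(cohort.X.head(800), y[:800])
        d = model.to_dict()
        assert len(d["support_vectors"]) > 0
        assert d["kernel"] == "rbf" and d["gamma"] is not None
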