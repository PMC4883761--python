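"""Splitting, metrics, calibration, model comparison, experiment harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import postoprisk as pk
from conftest import brute_force_auc


class TestStratifiedSplit:
    def test_allocation_and_counts(self):
        y = np.r_[np.ones(36, dtype=int), np.zeros(64, dtype=int)]
        plan = pk.stratified_split(y, 0.7, seed=0)
        assert len(plan.train_idx) == 70
        assert y[plan.train_idx].sum() == 25  # round(0.7 * 36)
        assert len(np.intersect1d(plan.train_idx, plan.val_idx)) == 0
        assert len(plan.train_idx) + len(plan.val_idx) == 100

    def test_same_seed_same_plan(self):
        y = np.random.default_rng(1).binomial(1, 0.3, 500)
        p1 = pk.stratified_split(y, seed=7)
        p2 = pk.stratified_split(y, seed=7)
        assert np.array_equal(p1.train_idx, p2.train_idx)

    def test_prevalence_preserved(self):
        y = np.random.default_rng(2).binomial(1, 0.36, 2000)
        plan = pk.stratified_split(y, 0.7, seed=3)
        for idx in (plan.train_idx, plan.val_idx):
            assert abs(y[idx].mean() - y.mean()) < 0.005

    def test_stratification_beats_simple_split(self):
        rng = np.random.default_rng(4)
        y = rng.binomial(1, 0.36, 400)
        strat, simple = [], []
        for rep in range(50):
            plan = pk.stratified_split(y, 0.7, seed=rep)
            strat.append(y[plan.val_idx].mean())
            idx = rng.permutation(400)
            simple.append(y[idx[280:]].mean())
        assert np.std(strat) < np.std(simple)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            pk.stratified_split(np.array([0, 0, 0, 1]), seed=0)


class TestAuc:
    def test_worked_example(self):
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert pk.auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert pk.auc(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, 0, 0])) == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=100)
        y = rng.binomial(1, 0.4, 100)
        assert pk.auc(s, y) == pytest.approx(1 - pk.auc(s, 1 - y))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            s = rng.integers(0, 5, 60).astype(float)  # heavy ties
            y = rng.binomial(1, 0.5, 60)
            if y.min() == y.max():
                continue
            assert pk.auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        s = rng.normal(size=300)
        y = rng.binomial(1, 0.3, 300)
        assert pk.auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            pk.auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestAccuracyPpv:
    def test_all_correct(self):
        acc, ppv = pk.accuracy_ppv(np.array([0.9, 0.1]), np.array([1, 0]))
        assert acc == 1.0 and ppv == 1.0

    def test_confusion_counts_example(self):
        # TP=30, FP=10, TN=50, FN=10
        scores = np.r_[np.full(30, 0.9), np.full(10, 0.9), np.full(50, 0.1), np.full(10, 0.1)]
        labels = np.r_[np.ones(30), np.zeros(10), np.zeros(50), np.ones(10)].astype(int)
        acc, ppv = pk.accuracy_ppv(scores, labels)
        assert acc == pytest.approx(0.80)
        assert ppv == pytest.approx(0.75)

    def test_no_predicted_positives_gives_nan_ppv(self):
        acc, ppv = pk.accuracy_ppv(np.array([0.3, 0.2]), np.array([0, 1]), threshold=1.01)
        assert np.isnan(ppv)


class TestBootstrapCi:
    def test_constant_metric_zero_width(self):
        s = np.array([1.0, 0.0] * 50)
        y = np.array([1, 0] * 50)
        pt, lo, hi = pk.bootstrap_ci(pk.auc, s, y, B=200, seed=0)
        assert pt == lo == hi == 1.0

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            pk.bootstrap_ci(pk.auc, np.zeros(10), np.r_[np.ones(5), np.zeros(5)], B=50)

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(8)
        widths = []
        for n in (500, 5000):
            y = rng.binomial(1, 0.4, n)
            s = rng.normal(size=n) + y
            _, lo, hi = pk.bootstrap_ci(pk.auc, s, y, B=300, seed=1)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_statistic_zero(self):
        # probabilities exactly equal to the group event rates
        p = np.r_[np.full(100, 0.2), np.full(100, 0.8)]
        y = np.r_[np.ones(20), np.zeros(80), np.ones(80), np.zeros(20)].astype(int)
        stat, pv = pk.hosmer_lemeshow(p, y, groups=2)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pv == pytest.approx(1.0)

    def test_miscalibration_detected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10_000, 2))
        p = expit(-0.5 + X @ np.array([0.9, 0.6]))
        y = rng.binomial(1, p)
        _, pv = pk.hosmer_lemeshow(p**2, y)
        assert pv < 1e-6

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            pk.hosmer_lemeshow(np.array([0.5, 1.2]), np.array([0, 1]))


class TestCompareModels:
    def test_identical_models_p_one(self):
        assert pk.compare_models([0.8] * 10, [0.8] * 10) == 1.0

    def test_separated_models_significant(self):
        rng = np.random.default_rng(10)
        a = 0.85 + rng.normal(0, 0.005, 50)
        b = 0.55 + rng.normal(0, 0.005, 50)
        assert pk.compare_models(a, b) < 0.01

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(11)
        a = 0.8 + rng.normal(0, 0.01, 30)
        b = 0.78 + rng.normal(0, 0.01, 30)
        assert pk.compare_models(a, b) == pytest.approx(pk.compare_models(b, a))

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            pk.compare_models([0.8, 0.9], [0.7])


class TestRiskFunctionCurves:
    @pytest.fixture(scope="class")
    def fitted_pair(self):
        cohort, _ = pk.make_gaussian_cohort(
            8000, linear={"xl": 0.8}, quadratic={"xq": (1.0, 0.0)}, seed=23
        )
        y = cohort.outcomes["y"].to_numpy()
        gam, diag = pk.fit_gam(cohort.X, y, smooth_features=["xq"], search="shared")
        lr = pk.fit_logistic(cohort.X, y)
        return gam, lr, diag

    def test_one_row_per_grid_point(self, fitted_pair, tmp_path):
        gam, lr, diag = fitted_pair
        grid = np.linspace(-2, 2, 41)
        table = pk.risk_function_curves(
            gam, lr, "xq", grid, edf=diag.edf.get("xq"),
            out_csv=tmp_path / "curve.csv", out_png=tmp_path / "curve.png",
        )
        assert len(table) == 41
        assert (tmp_path / "curve.csv").exists()
        assert (tmp_path / "curve.png").exists()

    def test_ushape_nonmonotone_logistic_monotone(self, fitted_pair):
        gam, lr, _ = fitted_pair
        grid = np.linspace(-2, 2, 41)
        table = pk.risk_function_curves(gam, lr, "xq", grid)
        g = table["gam_effect"].to_numpy()
        l = table["logistic_effect"].to_numpy()
        assert np.all(np.diff(l) >= 0) or np.all(np.diff(l) <= 0)
        assert not (np.all(np.diff(g) >= 0) or np.all(np.diff(g) <= 0))
        assert abs(grid[np.argmin(g)]) < 0.5

    def test_absent_feature_rejected(self, fitted_pair):
        gam, lr, _ = fitted_pair
        with pytest.raises(ValueError):
            pk.risk_function_curves(gam, lr, "nope", np.linspace(-1, 1, 5))


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        spec = pk.default_cohort_spec(n_patients=1500, seed=17)
        cohort, _ = pk.generate_cohort(spec)
        return cohort

    def test_smoke_and_row_count(self, small_cohort):
        cfg = pk.ExperimentConfig(
            models=("logistic", "naive_bayes"),
            arms=("none", "pca"),
            outcomes=("aki",),
            repetitions=1,
            bootstrap_B=100,
            min_count=30,
        )
        report = pk.run_experiment(small_cohort, cfg)
        assert len(report.table) == 2 * 2 * 1
        required = {"model", "arm", "outcome", "auc_mean", "accuracy_mean",
                    "auc_boot_lo", "auc_boot_hi", "hl_stat"}
        assert required <= set(report.table.columns)
        assert ((report.table["auc_mean"] >= 0) & (report.table["auc_mean"] <= 1)).all()

    def test_repetition_mean_order_invariant(self, small_cohort):
        cfg = pk.ExperimentConfig(
            models=("logistic",), arms=("none",), outcomes=("aki",),
            repetitions=3, bootstrap_B=100, min_count=30,
        )
        r1 = pk.run_experiment(small_cohort, cfg)
        aucs = r1.per_rep_auc[("logistic", "none", "aki")]
        assert r1.table["auc_mean"].iloc[0] == pytest.approx(np.mean(aucs))

    def test_paper_mode_optimistic_vs_honest(self):
        # whole-cohort target encoding leaks outcome into validation scores
        spec = pk.default_cohort_spec(n_patients=3000, seed=29)
        cohort, _ = pk.generate_cohort(spec)
        common = dict(
            models=("logistic",), arms=("none",), outcomes=("aki",),
            repetitions=2, bootstrap_B=100, min_count=50, seed=5,
        )
        honest = pk.run_experiment(cohort, pk.ExperimentConfig(**common))
        paper = pk.run_experiment(
            cohort, pk.ExperimentConfig(paper_mode=True, **common)
        )
        a_honest = honest.per_rep_auc[("logistic", "none", "aki")]
        a_paper = paper.per_rep_auc[("logistic", "none", "aki")]
        assert np.all(a_paper >= a_honest - 1e-9)

    def test_unknown_outcome_rejected(self, small_cohort):
        cfg = pk.ExperimentConfig(outcomes=("nope",), repetitions=1)
        with pytest.raises(ValueError):
            pk.run_experiment(small_cohort, cfg)
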