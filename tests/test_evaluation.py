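"""ROC/AUROC, DeLong comparison, PPV calibration, t-tests, validation, swap."""

import numpy as np
import pytest

import nncascade as nc
from nncascade.evaluation import delong_variance

from conftest import brute_force_auroc, textbook_ttest


class TestAuroc:
    def test_perfect_separation(self):
        assert nc.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert nc.auroc(np.full(6, 0.5), [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            assert nc.auroc(scores, y) == pytest.approx(
                brute_force_auroc(scores, y), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            nc.auroc([0.1, 0.2], [1, 1])


class TestRocCurve:
    def test_sensitivity_specificity_monotone_in_threshold(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.uniform(0, 1, n), 1)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            curve = nc.roc_curve(scores, y)
            # thresholds descend: sensitivity rises, specificity falls
            assert np.all(np.diff(curve.sensitivity) >= 0)
            assert np.all(np.diff(curve.specificity) <= 0)

    def test_auroc_equals_mann_whitney_normalization(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        y = np.array([1, 0, 1, 0])
        curve = nc.roc_curve(scores, y)
        assert curve.auroc == pytest.approx(brute_force_auroc(scores, y), abs=1e-12)
        assert curve.n_pos == 2 and curve.n_neg == 2
        assert curve.auroc_se > 0

    def test_sentinel_threshold_predicts_nobody_positive(self):
        curve = nc.roc_curve([0.1, 0.9], [0, 1])
        assert curve.sensitivity[0] == 0.0 and curve.specificity[0] == 1.0


class TestDeLong:
    def test_identical_scores_give_zero_delta_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0, 1, 20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        delta, p = nc.compare_auroc_paired(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_reversed_scores_symmetry(self):
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        y = np.array([0, 0, 0, 1, 1, 1])
        delta, _ = nc.compare_auroc_paired(s, 1 - s, y)
        assert delta == pytest.approx(2 * nc.auroc(s, y) - 1, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nc.compare_auroc_paired([0.1, 0.2], [0.1], [0, 1])

    def test_variance_matches_bootstrap_oracle_within_ten_percent(self):
        rng = np.random.default_rng(77)
        n = 30
        scores = rng.uniform(0, 1, n)
        y = (scores + rng.normal(0, 0.4, n) > 0.5).astype(int)
        y[:2] = [0, 1]
        var_delong = delong_variance(scores, y)
        boot = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            boot.append(nc.auroc(scores[idx], y[idx]))
        var_boot = float(np.var(boot, ddof=1))
        assert var_delong == pytest.approx(var_boot, rel=0.10)

    def test_discriminating_vs_noise_scores_yields_small_p(self):
        rng = np.random.default_rng(5)
        y = np.array([0] * 30 + [1] * 30)
        good = y + rng.normal(0, 0.3, 60)
        noise = rng.uniform(0, 1, 60)
        _, p = nc.compare_auroc_paired(good, noise, y)
        assert p < 0.01


class TestPpv:
    curve = staticmethod(
        lambda: nc.roc_curve([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
    )

    def test_criterion_below_all_scores_returns_prevalence(self):
        assert nc.ppv_at_criterion(self.curve(), 0.0) == 0.5

    def test_criterion_above_all_scores_is_undefined(self):
        assert np.isnan(nc.ppv_at_criterion(self.curve(), 0.99))

    def test_direct_count_at_intermediate_criterion(self):
        # samples >= 0.5: scores 0.9 (dead) and 0.8 (alive) -> PV = 1/2
        assert nc.ppv_at_criterion(self.curve(), 0.5) == 0.5

    def test_poor_prognosis_probability_extremes(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        curve = nc.roc_curve(scores, y)
        probs = nc.poor_prognosis_probability(curve, [0.9, 0.0])
        assert probs[0] == 1.0  # training max held only by dead samples
        assert probs[1] == 0.5  # below the minimum: prevalence

    def test_monotone_in_new_score_on_separable_reference(self):
        scores = np.linspace(0, 1, 12)
        y = (scores > 0.5).astype(int)
        curve = nc.roc_curve(scores, y)
        grid = np.linspace(0, 1, 50)
        probs = nc.poor_prognosis_probability(curve, grid)
        assert np.all(np.diff(probs) >= 0)


class TestGroupTtest:
    def test_matches_textbook_computation(self):
        rng = np.random.default_rng(10)
        g0 = rng.normal(0, 1, 10)
        g1 = rng.normal(0.8, 1, 10)
        values = np.concatenate([g0, g1])
        y = np.array([0] * 10 + [1] * 10)
        res = nc.group_ttest(values, y)
        t_exp, p_exp = textbook_ttest(g1, g0)
        assert res.t_statistic == pytest.approx(t_exp, abs=1e-10)
        assert res.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_identical_groups_have_p_one(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        res = nc.group_ttest(values, y)
        assert res.p_value == pytest.approx(1.0)

    def test_forced_separation_has_tiny_p(self):
        values = np.array([0.0, 0.001, -0.001, 1.0, 1.001, 0.999])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert nc.group_ttest(values, y).p_value < 0.001

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            nc.group_ttest([1.0, 2.0, 3.0], [0, 0, 1])


class TestInternalValidation:
    def test_identical_seed_gives_identical_report(self, small_fitted):
        cohort = small_fitted["cohort"]
        spec = nc.ModelSpec(kind="nnc", k=9)
        a = nc.internal_validate(cohort, spec, seed=4)
        b = nc.internal_validate(cohort, spec, seed=4)
        assert a.auroc_test == b.auroc_test
        assert a.unit_tr == b.unit_tr and a.unit_te == b.unit_te

    def test_part_sizes_follow_the_ratio(self, small_fitted):
        report = nc.internal_validate(small_fitted["cohort"], nc.ModelSpec(k=9), seed=4)
        assert report.part_sizes == (120, 60, 60)

    def test_tr_te_reported_for_every_unit(self, small_fitted):
        report = nc.internal_validate(small_fitted["cohort"], nc.ModelSpec(k=9), seed=4)
        assert [len(layer) for layer in report.unit_tr] == [9, 3, 1]
        assert [len(layer) for layer in report.unit_te] == [9, 3, 1]

    def test_tiny_cohort_with_single_class_part_rejected(self):
        cohort = nc.Cohort(
            [f"s{i}" for i in range(6)],
            ["f"],
            np.random.default_rng(0).uniform(size=(1, 6)),
            np.array([0, 0, 0, 0, 0, 1]),
        )
        with pytest.raises(ValueError, match="single class"):
            nc.internal_validate(cohort, nc.ModelSpec(kind="unn", k=1), seed=0)


class TestSwapExperiment:
    def test_identity_swap_leaves_predictions_unchanged(self, small_fitted):
        model = small_fitted["fitted"].model
        ext = small_fitted["ext"]
        target = model.feature_ids[0]
        res = nc.swap_experiment({"nnc": model}, ext, target, source=target)
        assert np.array_equal(
            res.predictions_after["nnc"], nc.predict_cascade(model, ext)
        )
        assert res.auroc_drop("nnc") == 0.0

    def test_swapped_column_equals_the_source_column(self, small_fitted):
        ext = small_fitted["ext"]
        model = small_fitted["fitted"].model
        target, source = model.feature_ids[0], model.feature_ids[1]
        res = nc.swap_experiment({"nnc": model}, ext, target, source=source)
        ti = ext.feature_ids.index(target)
        si = ext.feature_ids.index(source)
        assert np.array_equal(res.perturbed.expression[ti], ext.expression[si])

    def test_unknown_feature_rejected(self, small_fitted):
        with pytest.raises(ValueError, match="nope"):
            nc.swap_experiment(
                {"m": small_fitted["fitted"].model}, small_fitted["ext"], "nope"
            )

    def test_uniform_noise_swap_is_seed_deterministic(self, small_fitted):
        model = small_fitted["fitted"].model
        ext = small_fitted["ext"]
        target = model.feature_ids[0]
        a = nc.swap_experiment({"m": model}, ext, target, "uniform-noise", seed=9)
        b = nc.swap_experiment({"m": model}, ext, target, "uniform-noise", seed=9)
        assert np.array_equal(a.predictions_after["m"], b.predictions_after["m"])
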