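"""Cascade planning, training, prediction and the flat baselines."""

import math

import numpy as np
import pytest

import nncascade as nc


def brute_force_plan_sizes(k: int, f: int) -> list[int]:
    """Independent grouping enumerator: chunk a row of k items into runs of
    at most f, merging a trailing singleton, until one run remains."""
    sizes = [k]
    cur = k
    while cur > 1:
        runs = []
        i = 0
        while i < cur:
            runs.append(min(f, cur - i))
            i += f
        if len(runs) > 1 and runs[-1] == 1:
            runs = runs[:-2] + [runs[-2] + 1]
        cur = len(runs)
        sizes.append(cur)
    return sizes


class TestPlanning:
    @pytest.mark.parametrize(
        "k,f,sizes,total",
        [
            (9, 3, [9, 3, 1], 13),
            (1, 3, [1], 1),
            (27, 3, [27, 9, 3, 1], 40),
            (4, 3, [4, 1], 5),  # trailing singleton merges into the last group
            (7, 3, [7, 2, 1], 10),
        ],
    )
    def test_layer_sizes_and_total_units(self, k, f, sizes, total):
        plan = nc.plan_cascade(k, f)
        assert plan.layer_sizes == sizes
        assert plan.total_units == total

    def test_matches_brute_force_enumerator_for_all_small_plans(self):
        for f in (2, 3, 4):
            for k in range(1, 31):
                plan = nc.plan_cascade(k, f)
                assert plan.layer_sizes == brute_force_plan_sizes(k, f), (k, f)
                # groups partition the layer below, in order, none of size 1
                for size, groups in zip(plan.layer_sizes, plan.grouping):
                    flat = [i for g in groups for i in g]
                    assert sorted(flat) == list(range(size))
                    if size > 1:
                        assert all(len(g) >= 2 for g in groups)

    def test_round_robin_grouping_covers_all_inputs(self):
        plan = nc.plan_cascade(9, 3, grouping="round-robin")
        assert plan.layer_sizes == [9, 3, 1]
        assert sorted(i for g in plan.grouping[0] for i in g) == list(range(9))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            nc.plan_cascade(0, 3)
        with pytest.raises(ValueError):
            nc.plan_cascade(5, 1)


class TestCascadeTraining:
    def test_unit_counts_match_the_plan(self, small_fitted):
        model = small_fitted["fitted"].model
        assert len(model.layer0_units) == 9
        assert [len(layer) for layer in model.upper_units] == [3, 1]
        assert model.n_units == 13

    def test_single_feature_cascade_equals_its_score_unit(self, small_fitted):
        train = small_fitted["train"]
        table = small_fitted["table"]
        ranking = nc.rank_and_select(table, train.outcome, k=1)
        model = nc.train_cascade(
            train, ranking, nc.plan_cascade(1, 3), seed=11, score_table=table
        )
        top = ranking.selected[0]
        expected = nc.score_unit(table.units[top], train.feature_values(top))
        assert np.array_equal(nc.predict_cascade(model, train), expected)

    def test_same_seed_gives_bit_identical_predictions(self, small_fitted):
        train, table = small_fitted["train"], small_fitted["table"]
        ranking = nc.rank_and_select(table, train.outcome, k=9)
        plan = nc.plan_cascade(9, 3)
        a = nc.train_cascade(train, ranking, plan, seed=3, score_table=table)
        b = nc.train_cascade(train, ranking, plan, seed=3, score_table=table)
        assert np.array_equal(nc.predict_cascade(a, train), nc.predict_cascade(b, train))

    def test_training_predictions_match_recorded_fit_scores(self, small_fitted):
        model = small_fitted["fitted"].model
        train = small_fitted["train"]
        assert np.array_equal(nc.predict_cascade(model, train), model.train_scores)

    def test_cascade_beats_its_single_features_on_training_data(self, small_fitted):
        model = small_fitted["fitted"].model
        train = small_fitted["train"]
        table = small_fitted["table"]
        cascade_auroc = nc.auroc(model.train_scores, train.outcome)
        for fid in model.feature_ids:
            idx = table.feature_ids.index(fid)
            assert cascade_auroc > nc.auroc(table.scores[idx], train.outcome)

    def test_plan_ranking_mismatch_rejected(self, small_fitted):
        train, table = small_fitted["train"], small_fitted["table"]
        ranking = nc.rank_and_select(table, train.outcome, k=3)
        with pytest.raises(ValueError, match="selected"):
            nc.train_cascade(train, ranking, nc.plan_cascade(9, 3), score_table=table)


class TestCascadePrediction:
    def test_output_in_unit_interval(self, small_fitted):
        s = nc.predict_cascade(small_fitted["fitted"].model, small_fitted["ext"])
        assert np.all((s >= 0) & (s <= 1))

    def test_midpoint_sample_gets_a_finite_score(self, small_fitted):
        model = small_fitted["fitted"].model
        ext = small_fitted["ext"]
        mid = nc.NormalizedCohort(
            sample_ids=["mid"],
            feature_ids=list(ext.feature_ids),
            expression=np.full((ext.n_features, 1), 0.5),
            outcome=np.array([0]),
            calibration=ext.calibration,
        )
        s = nc.predict_cascade(model, mid)
        assert np.isfinite(s[0]) and 0 <= s[0] <= 1

    def test_sample_permutation_equivariance(self, small_fitted):
        model = small_fitted["fitted"].model
        ext = small_fitted["ext"]
        perm = np.random.default_rng(1).permutation(ext.n_samples)
        s = nc.predict_cascade(model, ext)
        s_perm = nc.predict_cascade(model, ext.subset_samples(perm))
        assert np.array_equal(s_perm, s[perm])

    def test_missing_feature_error_names_it(self, small_fitted):
        model = small_fitted["fitted"].model
        ext = small_fitted["ext"]
        keep = [f for f in ext.feature_ids if f != model.feature_ids[0]]
        with pytest.raises(ValueError, match=model.feature_ids[0]):
            nc.predict_cascade(model, ext.subset_features(keep))

    def test_feature_relabeling_leaves_predictions_unchanged(self, small_fitted):
        train = small_fitted["train"]
        renamed = nc.NormalizedCohort(
            sample_ids=list(train.sample_ids),
            feature_ids=[f"renamed_{f}" for f in train.feature_ids],
            expression=train.expression.copy(),
            outcome=train.outcome.copy(),
            calibration=nc.FeatureCalibration(
                feature_ids=[f"renamed_{f}" for f in train.feature_ids],
                min_value=train.calibration.min_value.copy(),
                max_value=train.calibration.max_value.copy(),
                constant_flags=train.calibration.constant_flags.copy(),
            ),
        )
        t1 = nc.transform_all_features(train, seed=11)
        t2 = nc.transform_all_features(renamed, seed=11)
        r1 = nc.rank_and_select(t1, train.outcome, k=9)
        r2 = nc.rank_and_select(t2, renamed.outcome, k=9)
        m1 = nc.train_cascade(train, r1, nc.plan_cascade(9, 3), seed=11, score_table=t1)
        m2 = nc.train_cascade(renamed, r2, nc.plan_cascade(9, 3), seed=11, score_table=t2)
        assert np.array_equal(
            nc.predict_cascade(m1, train), nc.predict_cascade(m2, renamed)
        )


class TestFlatModels:
    def test_flat_unit_has_k_inputs(self, small_fitted):
        train, table = small_fitted["train"], small_fitted["table"]
        ranking = nc.rank_and_select(table, train.outcome, k=3)
        for mode in ("unn", "tnn"):
            model = nc.train_flat(train, ranking, mode, k=3, score_table=table)
            assert model.unit.input_dim == 3
            assert model.unit.architecture == "3-11-1"

    def test_unknown_mode_rejected(self, small_fitted):
        train, table = small_fitted["train"], small_fitted["table"]
        ranking = nc.rank_and_select(table, train.outcome, k=3)
        with pytest.raises(ValueError, match="mode"):
            nc.train_flat(train, ranking, "xnn", score_table=table)

    def test_flat_predictions_bounded(self, small_fitted):
        train, table, ext = (
            small_fitted["train"],
            small_fitted["table"],
            small_fitted["ext"],
        )
        ranking = nc.rank_and_select(table, train.outcome, k=3)
        for mode in ("unn", "tnn"):
            model = nc.train_flat(train, ranking, mode, k=3, score_table=table)
            s = nc.predict_flat(model, ext)
            assert np.all((s >= 0) & (s <= 1))


class TestModelSerialization:
    def test_cascade_round_trip_bit_exact(self, small_fitted, tmp_path):
        model = small_fitted["fitted"].model
        ext = small_fitted["ext"]
        path = tmp_path / "cascade.json"
        nc.save_model(model, str(path))
        loaded = nc.load_model(str(path))
        assert np.array_equal(nc.predict_cascade(model, ext), nc.predict_cascade(loaded, ext))
        assert loaded.plan.layer_sizes == model.plan.layer_sizes

    def test_flat_round_trip_bit_exact(self, small_fitted, tmp_path):
        train, table, ext = (
            small_fitted["train"],
            small_fitted["table"],
            small_fitted["ext"],
        )
        ranking = nc.rank_and_select(table, train.outcome, k=3)
        model = nc.train_flat(train, ranking, "tnn", k=3, score_table=table)
        path = tmp_path / "flat.json"
        nc.save_model(model, str(path))
        loaded = nc.load_model(str(path))
        assert np.array_equal(nc.predict_flat(model, ext), nc.predict_flat(loaded, ext))
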