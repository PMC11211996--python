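"""Grid search, weight optimisation, null benchmarks, CV and stability."""

import numpy as np
import pytest

from netspread import (
    CombinationWeights,
    ConnectomeCombinationModel,
    combine_connectomes,
    cross_validate,
    grid_search,
    default_time_grid,
    null_combination_test,
    null_distribution,
    optimize_weights,
    stability_analysis,
    synth_subject_connectomes,
)
from netspread.synthetic import SyntheticWorld, noiseless_pattern, synth_pathology

TIMES = default_time_grid(n_times=101)
SEED_SHORTLIST = ["entorhinal", "fusiform", "inferiortemporal",
                  "middletemporal", "supramarginal"]


class TestGridSearch:
    def test_recovers_generating_seed_and_threshold(self, world, measured):
        gs = grid_search(
            world.combined(), SEED_SHORTLIST, [0.5, 0.3, 0.1], measured,
            times=TIMES,
        )
        assert gs.best_seed == world.seed_region

    def test_single_cell_grid(self, world, measured):
        gs = grid_search(world.connectomes[0], ["entorhinal"], [0.3],
                         measured, times=TIMES)
        assert len(gs.table) == 1
        assert gs.best_seed == "entorhinal" and gs.best_threshold == 0.3

    def test_table_covers_full_grid(self, world, measured):
        gs = grid_search(world.connectomes[0], SEED_SHORTLIST[:3],
                         [0.5, 0.2], measured, times=TIMES)
        assert len(gs.table) == 6
        assert set(gs.table["seed"]) == set(SEED_SHORTLIST[:3])

    def test_empty_grid_rejected(self, world, measured):
        with pytest.raises(ValueError):
            grid_search(world.connectomes[0], [], [0.3], measured)


class TestOptimizeWeights:
    def test_one_hot_target_recovered(self, world):
        conns = world.thresholded()[:3]
        target = noiseless_pattern(world, conns[0])
        res = optimize_weights(
            conns, [world.seed_region], target,
            n_random=30, n_iter=30, rng_seed=5, times=TIMES,
        )
        lam = res.weights.as_array([c.modality for c in conns])
        assert lam[0] >= 0.9

    def test_twin_modality_dominance(self, world, measured):
        conns = world.thresholded()
        twin = conns[0].with_weights(conns[0].weights.copy(), "twin")
        res = optimize_weights(
            [conns[0], twin, conns[1]], [world.seed_region], measured,
            n_random=20, n_iter=20, rng_seed=2, times=TIMES,
        )
        from netspread import run_pipeline

        uni = run_pipeline(conns[0], world.seed_region, None, measured,
                           times=TIMES)
        assert res.fit.sse_opt <= uni.sse_opt + 1e-12

    def test_reproducibility_of_returned_fit(self, world, measured):
        conns = world.thresholded()
        res = optimize_weights(conns, [world.seed_region], measured,
                               n_random=15, n_iter=10, rng_seed=3,
                               times=TIMES)
        rebuilt = combine_connectomes(conns, res.weights)
        from netspread import run_pipeline

        refit = run_pipeline(rebuilt, res.seed_region, None, measured,
                             times=TIMES)
        assert refit.r_max == pytest.approx(res.fit.r_max, abs=1e-12)
        assert refit.sse_opt == pytest.approx(res.fit.sse_opt, abs=1e-12)

    def test_deterministic_given_seed(self, world, measured):
        conns = world.thresholded()
        a = optimize_weights(conns, [world.seed_region], measured,
                             n_random=10, n_iter=5, rng_seed=7, times=TIMES)
        b = optimize_weights(conns, [world.seed_region], measured,
                             n_random=10, n_iter=5, rng_seed=7, times=TIMES)
        assert a.to_dict() == b.to_dict()
        np.testing.assert_array_equal(
            [x for _, x, _ in a.trace], [x for _, x, _ in b.trace]
        )

    def test_budget_too_small_rejected(self, world, measured):
        with pytest.raises(ValueError):
            ConnectomeCombinationModel(
                world.thresholded(), measured, ["entorhinal"],
                n_random=1, n_iter=1,
            )


class TestNullDistribution:
    def test_single_null_percentile_degenerate(self, world, measured):
        res = null_distribution(
            world.connectomes[0], measured, "inferiortemporal", 0.3,
            n_nulls=1, rng_seed=0, times=TIMES,
        )
        assert res.percentile_rank in (0.0, 100.0)

    def test_observed_beats_nulls_on_model_generated_target(self, world):
        c = world.combined()
        target = noiseless_pattern(world)
        res = null_distribution(
            c, target, world.seed_region, None, n_nulls=30, rng_seed=1,
            times=TIMES,
        )
        assert res.observed_rmax > np.percentile(res.null_rmax, 95)

    def test_deterministic(self, world, measured):
        a = null_distribution(world.connectomes[1], measured,
                              "entorhinal", 0.3, 5, 42, times=TIMES)
        b = null_distribution(world.connectomes[1], measured,
                              "entorhinal", 0.3, 5, 42, times=TIMES)
        np.testing.assert_array_equal(a.null_rmax, b.null_rmax)


class TestNullCombination:
    def test_single_repeat(self, world, measured):
        conns = world.thresholded()
        vals = null_combination_test(
            conns[:1], conns[1:], measured, [world.seed_region],
            n_repeats=1, rng_seed=0, n_random=8, n_iter=4, times=TIMES,
        )
        assert vals.shape == (1,)

    def test_rewired_partners_underperform_true_combination(self, world):
        target = synth_pathology(world, rng_seed=21)
        conns = world.thresholded()
        true_res = optimize_weights(
            conns, [world.seed_region], target,
            n_random=20, n_iter=15, rng_seed=4, times=TIMES,
        )
        null_vals = null_combination_test(
            conns[:1], conns[1:], target, [world.seed_region],
            n_repeats=5, rng_seed=4, n_random=20, n_iter=15, times=TIMES,
        )
        assert np.median(null_vals) < true_res.fit.r_max


class TestCrossValidation:
    def test_homogeneous_cohort_train_equals_test(self, world):
        pattern = synth_pathology(world)
        cohort = [pattern] * 10
        res = cross_validate(
            cohort, [world.connectomes[0], world.connectomes[1]],
            k=5, seeds=["inferiortemporal"], thresholds=[0.3],
            rng_seed=0, n_random=8, n_iter=4, times=TIMES,
        )
        for _, row in res.folds.iterrows():
            assert row["train_rmax"] == pytest.approx(row["test_rmax"],
                                                      abs=1e-12)

    def test_folds_partition_subjects(self, world):
        cohort = synth_pathology(world, n_subjects=17, rng_seed=2)
        res = cross_validate(
            cohort, [world.connectomes[0], world.connectomes[2]],
            k=5, seeds=["inferiortemporal"], thresholds=[0.3],
            rng_seed=1, n_random=8, n_iter=4, times=TIMES,
        )
        assert res.fold_assignment.size == 17
        counts = np.bincount(res.fold_assignment, minlength=5)
        assert counts.min() >= 3 and counts.sum() == 17

    def test_too_few_folds_rejected(self, world, measured):
        with pytest.raises(ValueError):
            cross_validate([measured] * 6, world.connectomes, k=1)


class TestStability:
    def test_identical_connectomes_zero_sd(self, world, measured):
        subs = [world.connectomes[0]] * 10
        res = stability_analysis(subs, measured, "inferiortemporal", 0.3,
                                 n_subsample=5, n_repeats=10, rng_seed=0,
                                 times=TIMES)
        assert res.sd == 0.0

    def test_sd_shrinks_with_subject_noise(self, world, measured):
        truth = world.connectomes[0]
        sds = []
        for noise in (0.3, 0.1, 0.02):
            subs = synth_subject_connectomes(truth, 20, noise, rng_seed=8)
            res = stability_analysis(
                subs, measured, "inferiortemporal", 0.3,
                n_subsample=8, n_repeats=15, rng_seed=9, times=TIMES,
            )
            sds.append(res.sd)
        assert sds[0] > sds[2]
        assert sds[1] >= sds[2] or sds[0] > sds[1]

    def test_subsample_larger_than_cohort_rejected(self, world, measured):
        with pytest.raises(ValueError):
            stability_analysis([world.connectomes[0]] * 3, measured,
                               "entorhinal", 0.3, n_subsample=5, n_repeats=2)
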