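import math

import pytest

from hamclust.genome import ReadSet
from hamclust.optimization import (
    cohort_penalty,
    downsample_reads,
    grid_search,
    plateau_midpoint,
    robustness_curve,
)
from hamclust.penalty import penalty_bounds
from hamclust.ranking import rank_peaks
from hamclust.synthetic import (
    CohortSpec,
    simulate_cohort,
    simulate_reads,
    toy_peak_caller,
)


class TestPlateauMidpoint:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([60000, 62000, 64000, 66000, 68000], 64000),
            ([12000], 12000),
            ([2000, 4000], 2000),  # even run: lower median
            ([2000, 4000, 6000, 20000], 4000),  # longest run wins
            ([2000, 10000, 12000, 30000, 32000], 10000),  # first longest on tie
        ],
    )
    def test_midpoint_rules(self, values, expected):
        assert plateau_midpoint(values) == expected

    def test_explicit_step_overrides_gap_inference(self):
        # with step 2000 the three values form two runs, not one
        assert plateau_midpoint([2000, 4000, 10000], step=2000) == 2000

    def test_empty_and_unsorted_rejected(self):
        with pytest.raises(ValueError):
            plateau_midpoint([])
        with pytest.raises(ValueError):
            plateau_midpoint([4000, 2000])


class TestDownsampleReads:
    @pytest.fixture
    def reads(self):
        return ReadSet(tuple(("chr1", i, i + 10) for i in range(1, 101, 10)))

    @pytest.mark.parametrize("r,remaining", [(0.0, 10), (0.25, 7), (1.0, 0)])
    def test_ceiling_removal_counts(self, reads, r, remaining):
        assert downsample_reads(reads, r, seed=1).count == remaining

    def test_r_zero_is_identity(self, reads):
        assert downsample_reads(reads, 0.0, seed=5) is reads

    def test_same_seed_bit_reproducible(self, reads):
        a = downsample_reads(reads, 0.5, seed=42)
        b = downsample_reads(reads, 0.5, seed=42)
        assert a.reads == b.reads

    def test_different_seeds_same_size(self, reads):
        a = downsample_reads(reads, 0.5, seed=1)
        b = downsample_reads(reads, 0.5, seed=2)
        assert a.count == b.count

    def test_survivors_keep_original_order_and_membership(self, reads):
        sub = downsample_reads(reads, 0.3, seed=3)
        it = iter(reads.reads)
        assert all(any(rd == x for x in it) for rd in sub.reads)

    @pytest.mark.parametrize("r", [-0.1, 1.1])
    def test_invalid_fraction(self, reads, r):
        with pytest.raises(ValueError):
            downsample_reads(reads, r, seed=0)


class TestGridSearch:
    def test_planted_cohort_recovers_zero_penalty_plateau(self, default_spec, default_cohort):
        """Grid search on the planted cohort: the minimizing plateau must
        contain the archetype size and reach penalty zero there."""
        ranked, cohort = default_cohort
        grid = [100, 200, 300, 400, 500, 600]
        res = grid_search({default_spec.p_G: ranked}, cohort, grid, default_spec.layout)
        assert res.min_penalty == 0
        minimizers = [m for (m, _) in res.argmin]
        assert default_spec.k_info in minimizers
        assert res.selected[0] in minimizers
        assert res.selected[1] == default_spec.p_G
        lo, hi = penalty_bounds(cohort)
        assert res.summary["lambda"].between(lo, hi).all()
        # selected point attains the grid minimum everywhere
        assert (res.summary["lambda"] >= res.min_penalty).all()

    def test_single_grid_point_selected(self, default_spec, default_cohort):
        ranked, cohort = default_cohort
        res = grid_search({default_spec.p_G: ranked}, cohort, [300], default_spec.layout)
        assert res.selected == (300, default_spec.p_G)

    def test_dense_noise_degrades_large_mcut(self):
        """With noise dense enough to swamp the type signal, keeping every
        peak must cluster worse than truncating at the archetype size."""
        spec = CohortSpec(k_info=60, k_noise=1500, samples_per_type=3,
                         shared_fraction=0.9, width_range=(30, 60), seed=3)
        ranked, cohort = simulate_cohort(spec)
        lam_at_k = cohort_penalty(ranked, cohort, spec.k_info, spec.layout)
        lam_all = cohort_penalty(ranked, cohort, math.inf, spec.layout)
        assert lam_at_k == 0
        assert lam_all > 0

    def test_empty_grid_rejected(self, default_spec, default_cohort):
        ranked, cohort = default_cohort
        with pytest.raises(ValueError):
            grid_search({default_spec.p_G: ranked}, cohort, [], default_spec.layout)


class TestRobustness:
    @pytest.fixture
    def small_world(self):
        spec = CohortSpec(samples_per_type=2, k_info=60, k_noise=30,
                         types=("HSC", "B"), seed=11)
        ranked, cohort = simulate_cohort(spec)
        # interleave types so that when read loss destroys all structure the
        # tie-broken merges cannot accidentally reunite same-type pairs
        order = ["HSC1", "B1", "HSC2", "B2"]
        reads = {
            s: simulate_reads(ranked[s], spec.layout, depth_per_peak=15, seed=i)
            for i, s in enumerate(order)
        }
        caller = lambda rs, pg: toy_peak_caller(rs, spec.layout, coverage_threshold=5, p_G=pg)
        return spec, cohort, reads, caller

    def test_r_zero_row_equals_baseline(self, small_world):
        spec, cohort, reads, caller = small_world
        baseline = cohort_penalty(
            {s: rank_peaks(caller(rs, spec.p_G), spec.layout, p_G=spec.p_G)
             for s, rs in reads.items()},
            cohort, 100, spec.layout,
        )
        tab = robustness_curve(reads, [0.0], seed=5, peak_caller=caller,
                               M_cut=100, p_G=spec.p_G, cohort=cohort,
                               layout=spec.layout, n_replicates=2)
        assert (tab["lambda"] == baseline).all()

    def test_small_loss_keeps_baseline_heavy_loss_destroys_structure(self, small_world):
        spec, cohort, reads, caller = small_world
        tab = robustness_curve(reads, [0.02, 0.98], seed=5, peak_caller=caller,
                               M_cut=100, p_G=spec.p_G, cohort=cohort,
                               layout=spec.layout, n_replicates=2)
        small = tab[tab.r == 0.02]["lambda"]
        heavy = tab[tab.r == 0.98]["lambda"]
        assert (small == 0).mean() >= 0.5
        assert (heavy > 0).all()

    def test_caller_failure_annotated_with_context(self, small_world):
        spec, cohort, reads, _ = small_world

        def broken(rs, pg):
            raise RuntimeError("caller exploded")

        with pytest.raises(RuntimeError, match=r"r=0\.5, replicate=0, sample="):
            robustness_curve(reads, [0.5], seed=1, peak_caller=broken,
                             M_cut=100, p_G=spec.p_G, cohort=cohort,
                             layout=spec.layout, n_replicates=1)
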