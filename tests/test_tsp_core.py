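"""Similarity mapping: Pearson correlation, seed maps, the iterative
automated map, threshold sweeps and lesion segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tspmap import (DynamicSeries, PhantomSpec, automated_tsp, dice,
                    generate_phantom, make_brain_mask, pearson_r,
                    seed_similarity_map, segment_lesion, threshold_sweep)
from tspmap.errors import IterationError, ParameterError, SeedError, ShapeError

from conftest import random_series_and_mask, small_spec

# frozen before the implementation: direct covariance / (sd_a * sd_b) formula
# evaluated on x = (1,2,3,4), y = (1,2,2,4)
PEARSON_ORACLE_1224 = 0.923380516876639


class TestPearsonR:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, x) == pytest.approx(1.0, abs=1e-15)

    def test_negative_affine_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, -2.0 * x + 7.0) == pytest.approx(-1.0, abs=1e-15)

    def test_matches_direct_formula_oracle(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 2, 4]) == pytest.approx(
            PEARSON_ORACLE_1224, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            pearson_r([1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(ShapeError):
            pearson_r([1, 2], [3, 4])

    def test_zero_variance_flagged_not_zeroed(self):
        assert np.isnan(pearson_r([1, 1, 1, 1], [1, 2, 3, 4]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 100.0), b=st.floats(-50.0, 50.0),
           seed=st.integers(0, 2**16))
    def test_positive_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        r0 = pearson_r(x, y)
        r1 = pearson_r(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestSeedSimilarityMap:
    def test_value_at_seed_is_one(self, stroke_phantom):
        series, _, mask = stroke_phantom
        seed = tuple(np.argwhere(mask.mask)[0])
        smap = seed_similarity_map(series, mask, seed)
        assert smap.values[seed] == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_healthy_seed_separates_lesion(self):
        series, gt = generate_phantom(small_spec(noise_sigma=0.0))
        mask = make_brain_mask(series, ventricle_mask=gt.ventricle_mask)
        healthy = mask.mask & ~gt.lesion_mask
        seed = tuple(np.argwhere(healthy)[100])
        smap = seed_similarity_map(series, mask, seed)
        assert np.nanmin(smap.values[healthy & smap.defined]) > 1.0 - 1e-9
        assert np.nanmax(smap.values[gt.lesion_mask & smap.defined]) < 1.0 - 1e-3

    def test_seed_inside_lesion_inverts_map(self, stroke_phantom):
        series, gt, mask = stroke_phantom
        lesion_in_mask = gt.lesion_mask & mask.mask
        seed = tuple(np.argwhere(lesion_in_mask)[lesion_in_mask.sum() // 2])
        smap = seed_similarity_map(series, mask, seed)
        mean_lesion = np.nanmean(smap.values[lesion_in_mask])
        mean_healthy = np.nanmean(smap.values[mask.mask & ~gt.lesion_mask])
        assert mean_lesion > mean_healthy

    def test_seed_outside_mask_rejected(self, stroke_phantom):
        series, _, mask = stroke_phantom
        outside = tuple(np.argwhere(~mask.mask)[0])
        with pytest.raises(SeedError):
            seed_similarity_map(series, mask, outside)

    def test_constant_seed_rejected(self, stroke_phantom):
        series, _, mask = stroke_phantom
        seed = tuple(np.argwhere(mask.mask)[0])
        doctored = DynamicSeries(data=series.data.copy(), tr=series.tr, te=series.te,
                                 voxel_dims=series.voxel_dims)
        doctored.data[seed] = 42.0
        with pytest.raises(SeedError):
            seed_similarity_map(doctored, mask, seed)

    def test_interactive_latency_at_protocol_size(self):
        # whole-map recompute must be much faster than 1 s at 80x80x20x80
        import time
        series, gt = generate_phantom(PhantomSpec(rng_seed=1))
        mask = make_brain_mask(series, ventricle_mask=gt.ventricle_mask)
        seed = tuple(np.argwhere(mask.mask & ~gt.lesion_mask)[500])
        seed_similarity_map(series, mask, seed)  # warm-up
        t0 = time.perf_counter()
        seed_similarity_map(series, mask, seed)
        assert time.perf_counter() - t0 < 1.0


class TestAutomatedTsp:
    def test_noise_free_fixpoint_all_ones(self, clean_phantom):
        series, _, mask = clean_phantom
        smap, history = automated_tsp(series, mask)
        assert np.all(np.abs(smap.values[smap.defined] - 1.0) < 1e-9)
        assert len(history) == 3  # initial reference + two refinements

    def test_lesion_lowers_r_and_segmentation_recovers_it(self, stroke_phantom):
        series, gt, mask = stroke_phantom
        smap, _ = automated_tsp(series, mask)
        lesion_in = gt.lesion_mask & smap.defined
        healthy_in = mask.mask & ~gt.lesion_mask & smap.defined
        assert np.mean(smap.values[lesion_in]) < np.mean(smap.values[healthy_in])
        seg = segment_lesion(smap, voxel_dims=series.voxel_dims)
        assert dice(seg, gt.lesion_mask & mask.mask) >= 0.90

    def test_extra_refinement_is_fixpoint(self, stroke_phantom):
        series, _, mask = stroke_phantom
        smap2, h2 = automated_tsp(series, mask, refinement_repeats=2)
        smap3, h3 = automated_tsp(series, mask, refinement_repeats=3)
        if h3[-1].n_voxels == h2[-1].n_voxels:  # mask stable -> map unchanged
            np.testing.assert_allclose(smap3.values[smap3.defined],
                                       smap2.values[smap2.defined], atol=1e-12)
        else:
            pytest.skip("refinement mask still changing at iteration 3")

    def test_contributing_counts_within_brain_mask(self, stroke_phantom):
        series, _, mask = stroke_phantom
        _, history = automated_tsp(series, mask)
        assert all(0 < h.n_voxels <= mask.n_voxels for h in history)

    def test_unreachable_threshold_reports_iteration(self):
        # pure-noise series: nothing correlates with the mean above 0.95
        rng = np.random.default_rng(0)
        series, mask = random_series_and_mask(rng, shape=(8, 8, 4), nt=30)
        with pytest.raises(IterationError) as exc:
            automated_tsp(series, mask, threshold=0.95)
        assert exc.value.iteration >= 1
        assert exc.value.threshold == 0.95

    def test_invalid_threshold_rejected(self, stroke_phantom):
        series, _, mask = stroke_phantom
        with pytest.raises(ParameterError):
            automated_tsp(series, mask, threshold=1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_voxel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        series, mask = random_series_and_mask(rng, shape=(6, 6, 4), nt=20)
        # seed map vs naive loop
        seed_vox = (2, 3, 1)
        smap = seed_similarity_map(series, mask, seed_vox)
        for idx in np.ndindex(*mask.shape):
            expected = pearson_r(series.data[idx], series.data[seed_vox])
            assert smap.values[idx] == pytest.approx(expected, abs=1e-10)
        # automated map vs naive loop replicating the iteration
        threshold = 0.2
        smap_auto, history = automated_tsp(series, mask, threshold=threshold)
        ref = series.data.reshape(-1, 20).mean(axis=0)
        values = None
        for _ in range(3):
            if values is not None:
                keep = values > threshold
                ref = series.data.reshape(-1, 20)[keep.ravel()].mean(axis=0)
            values = np.array([pearson_r(series.data[idx], ref)
                               for idx in np.ndindex(*mask.shape)]).reshape(mask.shape)
        np.testing.assert_allclose(smap_auto.values, values, atol=1e-10)

    def test_affine_rescaling_of_one_voxel_leaves_its_value(self, stroke_phantom):
        # exact for the seed map (reference independent of the voxel); the
        # iterative map's reference average shifts infinitesimally when one
        # of tens of thousands of contributing voxels is rescaled, so there
        # the invariance is asserted as stability
        series, _, mask = stroke_phantom
        vox = tuple(np.argwhere(mask.mask)[42])
        seed = tuple(np.argwhere(mask.mask)[-1])
        scaled = DynamicSeries(data=series.data.copy(), tr=series.tr, te=series.te,
                               voxel_dims=series.voxel_dims)
        scaled.data[vox] = 3.7 * scaled.data[vox] + 11.0

        sm_seed = seed_similarity_map(series, mask, seed)
        sm_seed2 = seed_similarity_map(scaled, mask, seed)
        assert sm_seed2.values[vox] == pytest.approx(sm_seed.values[vox], abs=1e-12)

        smap, _ = automated_tsp(series, mask)
        smap2, _ = automated_tsp(scaled, mask)
        assert smap2.values[vox] == pytest.approx(smap.values[vox], abs=1e-3)

    def test_map_values_bounded(self, stroke_phantom):
        series, _, mask = stroke_phantom
        smap, _ = automated_tsp(series, mask)
        vals = smap.values[smap.defined]
        assert np.all(vals >= -1.0) and np.all(vals <= 1.0)
        assert not np.any(np.isnan(vals))


class TestThresholdSweep:
    def test_single_threshold_matches_automated_default(self, stroke_phantom):
        series, _, mask = stroke_phantom
        maps, _ = threshold_sweep(series, mask, thresholds=[0.6])
        smap, _ = automated_tsp(series, mask, threshold=0.6)
        np.testing.assert_array_equal(maps[0.6].values[maps[0.6].defined],
                                      smap.values[smap.defined])

    def test_healthy_mean_stable_across_thresholds(self, stroke_phantom):
        series, gt, mask = stroke_phantom
        _, stats = threshold_sweep(series, mask, lesion_mask=gt.lesion_mask)
        healthy_means = [row["mean_healthy"] for row in stats]
        assert max(healthy_means) - min(healthy_means) < 0.05
        assert [row["threshold"] for row in stats] == [0.5, 0.6, 0.7, 0.8, 0.9]

    def test_out_of_range_threshold_rejected(self, stroke_phantom):
        series, _, mask = stroke_phantom
        with pytest.raises(ParameterError):
            threshold_sweep(series, mask, thresholds=[0.5, 1.2])


class TestSegmentLesion:
    def test_lesion_free_noisy_phantom_yields_empty_mask(self, tia_phantom):
        series, _, mask = tia_phantom
        smap, _ = automated_tsp(series, mask)
        seg = segment_lesion(smap, cutoff=0.6, min_cluster_volume_mm3=1000.0,
                             voxel_dims=series.voxel_dims)
        assert not seg.any()

    def test_cutoff_minus_one_yields_empty_mask(self, stroke_phantom):
        series, _, mask = stroke_phantom
        smap, _ = automated_tsp(series, mask)
        assert not segment_lesion(smap, cutoff=-1.0).any()

    def test_small_clusters_filtered_by_volume(self, stroke_phantom):
        series, gt, mask = stroke_phantom
        smap, _ = automated_tsp(series, mask)
        # poke a single isolated low-R voxel into a copy of the map
        values = smap.values.copy()
        healthy = mask.mask & ~gt.lesion_mask & smap.defined
        lone = tuple(np.argwhere(healthy)[7])
        values[lone] = -0.5
        doctored = type(smap)(values=values, defined=smap.defined)
        seg = segment_lesion(doctored, voxel_dims=series.voxel_dims)
        assert not seg[lone]

    def test_undefined_voxels_never_in_lesion(self, stroke_phantom):
        series, _, mask = stroke_phantom
        smap, _ = automated_tsp(series, mask)
        seg = segment_lesion(smap, voxel_dims=series.voxel_dims)
        assert not np.any(seg & ~smap.defined)
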