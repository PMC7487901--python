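import numpy as np
import pytest
from scipy.ndimage import maximum_filter
from scipy.stats import binom

from rhoquant.scene_sim import (
    CytometrySimParams,
    FretSceneParams,
    MatrixSceneParams,
    MotilitySceneParams,
    PlacementError,
    PunctaSceneParams,
    WoundSceneParams,
    make_cytometry_events,
    make_fret_scene,
    make_gel_lanes,
    make_matrix_scene,
    make_puncta_scene,
    make_track_set,
    make_wound_series,
)


class TestFretScene:
    def test_uniform_ratio_one_fret_equals_donor(self):
        p = FretSceneParams(noise_model="none", ratio_baseline=1.0, seed=0)
        s, mask, _ = make_fret_scene(p)
        np.testing.assert_array_equal(s.fret.pixels, s.donor.pixels)

    def test_uniform_ratio_16_pixelwise(self):
        p = FretSceneParams(noise_model="none", ratio_baseline=1.6,
                            background_level=0.0, seed=0)
        s, mask, _ = make_fret_scene(p)
        inside = mask.as_bool()
        np.testing.assert_allclose(
            s.fret.pixels[inside] / s.donor.pixels[inside], 1.6, rtol=1e-12
        )

    def test_hotspot_mean_ratio_brute_force(self):
        p = FretSceneParams(noise_model="none", hotspot_fraction=0.1,
                            hotspot_factor=2.0, seed=0)
        _, mask, truth = make_fret_scene(p)
        # independent oracle: recompute the mean from the returned map
        brute = truth.ratio_map[mask.as_bool()].mean()
        assert truth.mean_ratio == pytest.approx(brute, abs=0)
        assert truth.mean_ratio == pytest.approx(1.1, abs=2e-4)

    def test_determinism(self):
        p = FretSceneParams(gaussian_sigma=40.0, seed=11)
        s1, _, _ = make_fret_scene(p)
        s2, _, _ = make_fret_scene(p)
        np.testing.assert_array_equal(s1.donor.pixels, s2.donor.pixels)
        np.testing.assert_array_equal(s1.fret.pixels, s2.fret.pixels)

    def test_sigma_zero_matches_noiseless(self):
        a, _, _ = make_fret_scene(FretSceneParams(noise_model="gaussian",
                                                  gaussian_sigma=0.0, seed=0))
        b, _, _ = make_fret_scene(FretSceneParams(noise_model="none", seed=0))
        np.testing.assert_array_equal(a.donor.pixels, b.donor.pixels)

    def test_ellipse_out_of_bounds_rejected(self):
        p = FretSceneParams(center=(10.0, 128.0))
        with pytest.raises(ValueError, match="ellipse"):
            make_fret_scene(p)

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            FretSceneParams(donor_level=10.0, background_level=50.0)


class TestMatrixScene:
    def test_no_spots_uniform(self):
        r, _, truth = make_matrix_scene(MatrixSceneParams(seed=0))
        assert np.all(r.pixels == 1000.0)
        assert truth.degraded_fraction == 0.0

    def test_full_depth_spot_center_zero(self):
        p = MatrixSceneParams(spots=[(128.0, 128.0, 5.0, 1.0)], seed=0)
        r, _, _ = make_matrix_scene(p)
        assert r.pixels[128, 128] == 0.0

    def test_degraded_fraction_exact(self):
        p = MatrixSceneParams(degraded_fraction=0.25, seed=3)
        _, footprint, truth = make_matrix_scene(p)
        fp = footprint.as_bool()
        # brute-force oracle: count degraded pixels in the returned map
        frac = (truth.degradation_map[fp] > 0).mean()
        assert abs(frac - 0.25) <= 1.0 / fp.sum() + 1e-12
        assert truth.degraded_fraction == pytest.approx(frac, abs=0)

    def test_overlapping_spots_take_max_depth(self):
        p = MatrixSceneParams(
            spots=[(128.0, 128.0, 6.0, 0.3), (128.0, 128.0, 4.0, 0.8)], seed=0
        )
        _, _, truth = make_matrix_scene(p)
        assert truth.degradation_map[128, 128] == 0.8

    def test_truth_index_matches_brute_force(self):
        p = MatrixSceneParams(degraded_fraction=0.3, seed=5)
        _, footprint, truth = make_matrix_scene(p)
        fp = footprint.as_bool()
        cell_mean = (truth.matrix_level * (1 - truth.degradation_map))[fp].mean()
        assert truth.degradation_index == pytest.approx(
            truth.matrix_level / cell_mean, rel=1e-12
        )

    def test_determinism(self):
        p = MatrixSceneParams(degraded_fraction=0.2, noise_sigma=15.0, seed=9)
        r1, _, _ = make_matrix_scene(p)
        r2, _, _ = make_matrix_scene(p)
        np.testing.assert_array_equal(r1.pixels, r2.pixels)


class TestPunctaScene:
    def test_zero_puncta_background_only(self):
        p = PunctaSceneParams(n_puncta=0, seed=0)
        r, _, truth = make_puncta_scene(p)
        assert np.all(r.pixels == 100.0)
        assert truth.n_puncta == 0

    def test_exact_local_maximum_count(self):
        p = PunctaSceneParams(n_puncta=12, noise_sigma=0.0, seed=2)
        r, _, truth = make_puncta_scene(p)
        # exhaustive scan: strict local maxima above background
        img = r.pixels
        peaks = (img == maximum_filter(img, size=5)) & (img > 150.0)
        assert peaks.sum() == 12

    def test_doubling_peak_leaves_centers(self):
        p1 = PunctaSceneParams(n_puncta=8, peak_intensity=500.0, seed=4)
        p2 = PunctaSceneParams(n_puncta=8, peak_intensity=1000.0, seed=4)
        _, _, t1 = make_puncta_scene(p1)
        _, _, t2 = make_puncta_scene(p2)
        np.testing.assert_array_equal(t1.centers, t2.centers)

    def test_placement_failure_raises(self):
        p = PunctaSceneParams(shape=(64, 64), center=(32, 32), axes=(20, 20),
                              n_puncta=50, min_separation_px=30.0, seed=0)
        with pytest.raises(PlacementError):
            make_puncta_scene(p)

    def test_truth_area_convention(self):
        p = PunctaSceneParams(n_puncta=3, radius_px=(4.0, 4.0), seed=1)
        _, _, truth = make_puncta_scene(p)
        np.testing.assert_allclose(truth.areas_px, np.pi * 16.0)


class TestTrackSet:
    def test_zero_step_constant(self):
        p = MotilitySceneParams(n_cells=3, n_frames=10, step_len_um=0.0, seed=0)
        tt, truth = make_track_set(p)
        for tid in tt.track_ids:
            tr = tt.track(tid)
            assert tr["x"].nunique() == 1 and tr["y"].nunique() == 1
        assert (truth.per_track["total_path_um"] == 0).all()

    def test_full_persistence_straight_line(self):
        p = MotilitySceneParams(n_cells=2, n_frames=20, step_len_um=0.5,
                                persistence=1.0, seed=1)
        tt, truth = make_track_set(p)
        expected = 0.5 * 19
        np.testing.assert_allclose(truth.per_track["total_path_um"], expected)
        np.testing.assert_allclose(truth.per_track["net_um"], expected, rtol=1e-9)

    def test_control_speed_construction(self):
        # 0.3 um steps at 1-min frames -> truth speed 0.3 um/min
        p = MotilitySceneParams(n_cells=5, n_frames=121, step_len_um=0.3,
                                persistence=0.4, seed=2)
        _, truth = make_track_set(p)
        np.testing.assert_allclose(truth.per_track["speed_um_min"], 0.3, rtol=1e-12)

    def test_net_le_total(self):
        p = MotilitySceneParams(n_cells=50, n_frames=30, persistence=0.3, seed=3)
        _, truth = make_track_set(p)
        assert (truth.per_track["net_um"] <= truth.per_track["total_path_um"] + 1e-9).all()

    def test_noise_does_not_change_truth(self):
        a = MotilitySceneParams(n_cells=2, n_frames=15, noise_sigma_um=0.0, seed=7)
        b = MotilitySceneParams(n_cells=2, n_frames=15, noise_sigma_um=0.5, seed=7)
        _, ta = make_track_set(a)
        _, tb = make_track_set(b)
        np.testing.assert_array_equal(
            ta.per_track["total_path_um"], tb.per_track["total_path_um"]
        )


class TestWoundSeries:
    def test_zero_rate_identical_frames(self):
        p = WoundSceneParams(closure_rate_um_hr=0.0, roughness_um=3.0,
                             frame_times_hr=(0.0, 24.0, 48.0), seed=0)
        masks, _ = make_wound_series(p)
        for m in masks[1:]:
            np.testing.assert_array_equal(m.pixels, masks[0].pixels)

    def test_arithmetic_width(self):
        p = WoundSceneParams(initial_width_um=500.0, closure_rate_um_hr=5.0,
                             frame_times_hr=(0.0, 48.0), seed=0)
        _, truth = make_wound_series(p)
        assert truth.nominal_width_um[1] == pytest.approx(260.0)

    def test_closure_clipped_at_zero(self):
        p = WoundSceneParams(initial_width_um=100.0, closure_rate_um_hr=5.0,
                             frame_times_hr=(0.0, 100.0), seed=0)
        masks, truth = make_wound_series(p)
        assert truth.nominal_width_um[1] == 0.0
        assert np.all(masks[1].pixels == 1)

    def test_smooth_edges_uniform_width(self):
        p = WoundSceneParams(roughness_um=0.0, seed=0)
        masks, _ = make_wound_series(p)
        per_row = (masks[0].pixels == 0).sum(axis=1)
        assert per_row.min() == per_row.max()


class TestCytometryEvents:
    def test_pure_g0g1_tight(self):
        p = CytometrySimParams(n_events=500, fractions=(1.0, 0.0, 0.0),
                               cv=0.001, seed=0)
        ev, _ = make_cytometry_events(p, mode="cellcycle")
        assert np.all(np.abs(ev["pi"] - 100.0) < 2.0)

    def test_mixture_counts_within_binomial_bounds(self):
        p = CytometrySimParams(n_events=10_000, fractions=(0.6, 0.2, 0.2), seed=1)
        _, truth = make_cytometry_events(p, mode="cellcycle")
        for frac, emp in zip(truth.fractions, truth.empirical_fractions):
            lo = binom.ppf(0.005, 10_000, frac) / 10_000
            hi = binom.ppf(0.995, 10_000, frac) / 10_000
            assert lo <= emp <= hi

    def test_apoptosis_all_live_below_thresholds(self):
        p = CytometrySimParams(n_events=300, apoptosis_fractions=(1.0, 0.0, 0.0),
                               seed=2)
        ev, _ = make_cytometry_events(p, mode="annexin")
        mid = 10.0 ** (p.separation_decades / 2.0)
        assert (ev["annexin"] < mid).all() and (ev["pi"] < mid).all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            CytometrySimParams(fractions=(0.5, 0.2, 0.2))

    def test_determinism(self):
        p = CytometrySimParams(seed=4)
        e1, _ = make_cytometry_events(p, mode="cellcycle")
        e2, _ = make_cytometry_events(p, mode="cellcycle")
        assert e1.equals(e2)


class TestGelLanes:
    def test_equal_lanes_fold_one(self):
        _, truth = make_gel_lanes([2.0, 2.0], [1.0, 1.0])
        np.testing.assert_allclose(truth.fold_vs_first, [1.0, 1.0])

    def test_doubled_band(self):
        _, truth = make_gel_lanes([1.0, 2.0], [1.0, 1.0])
        assert truth.fold_vs_first[1] == pytest.approx(2.0)

    def test_exposure_invariance_of_truth_folds(self):
        _, t1 = make_gel_lanes([1.0, 2.5], [1.0, 1.0])
        _, t2 = make_gel_lanes([3.0, 7.5], [3.0, 3.0])
        np.testing.assert_allclose(t1.fold_vs_first, t2.fold_vs_first)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            make_gel_lanes([0.0, 1.0], [1.0, 1.0])
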