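import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rhoquant.img_io import Mask, Raster
from rhoquant.puncta_detect import (
    Puncta,
    PunctaSet,
    adhesion_area_fold,
    clahe,
    detect_puncta,
    invadopodia_count,
    line_profile,
    log_response,
)
from rhoquant.scene_sim import PunctaSceneParams, make_puncta_scene


def _spot_image(radius=3.0, peak=200.0, background=50.0, shape=(64, 64)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    s2 = (radius / np.sqrt(2.0)) ** 2
    cr, ccen = shape[0] / 2, shape[1] / 2
    return Raster(
        background + peak * np.exp(-((rr - cr) ** 2 + (cc - ccen) ** 2) / (2 * s2))
    )


class TestClahe:
    def test_constant_stays_constant(self):
        out = clahe(Raster(np.full((64, 64), 40.0)))
        assert np.ptp(out.pixels) == 0.0

    def test_output_range(self, rng):
        out = clahe(Raster(rng.uniform(0, 4095, size=(128, 128))))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_contrast_improves_on_low_contrast_spots(self):
        p = PunctaSceneParams(n_puncta=6, peak_intensity=30.0,
                              background_level=1000.0, noise_sigma=0.0, seed=1)
        raster, _, truth = make_puncta_scene(p)
        enhanced = clahe(raster)

        def contrast(r):
            peaks = [r.pixels[int(round(a)), int(round(b))] for a, b in truth.centers]
            return (np.mean(peaks) - np.median(r.pixels)) / np.ptp(r.pixels)

        assert contrast(enhanced) >= contrast(raster)

    def test_tile_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            clahe(Raster(np.ones((32, 32))), tile_px=64)

    def test_bad_params_rejected(self):
        r = Raster(np.ones((64, 64)))
        with pytest.raises(ValueError):
            clahe(r, tile_px=4)
        with pytest.raises(ValueError):
            clahe(r, clip_limit=0.0)


class TestLogResponse:
    def test_constant_zero_response(self):
        out = log_response(Raster(np.full((32, 32), 9.0)), sigma_px=2.0)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)

    def test_optimal_sigma_near_r_over_sqrt2(self):
        radius = 4.0
        raster = _spot_image(radius=radius)
        sigmas = np.arange(0.5, 8.0, 0.25)
        center = (raster.shape[0] // 2, raster.shape[1] // 2)
        responses = [log_response(raster, s).pixels[center] for s in sigmas]
        best = sigmas[int(np.argmax(responses))]
        assert best == pytest.approx(radius / np.sqrt(2.0), abs=0.5)

    def test_ramp_kills_response(self):
        ramp = np.tile(np.linspace(0, 100, 64), (64, 1))
        out = log_response(Raster(ramp), sigma_px=2.0)
        assert np.abs(out.pixels[10:-10, 10:-10]).max() < 1e-6

    def test_small_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_response(Raster(np.ones((16, 16))), sigma_px=0.1)


class TestDetectPuncta:
    def test_blank_noisy_image_no_puncta(self, rng):
        r = Raster(np.clip(rng.normal(100, 10, size=(128, 128)), 0, None))
        assert len(detect_puncta(r, k_mad=5.0)) == 0

    def test_twelve_spots_recovered(self):
        p = PunctaSceneParams(n_puncta=12, noise_sigma=100.0,
                              peak_intensity=500.0, seed=6)
        raster, mask, truth = make_puncta_scene(p)
        ps = detect_puncta(clahe(raster), mask)
        assert len(ps) == 12
        d = cdist(ps.centroids, truth.centers)
        assert d.min(axis=1).max() <= 1.0

    def test_max_area_filter_removes_all(self):
        p = PunctaSceneParams(n_puncta=5, noise_sigma=0.0, seed=0)
        raster, mask, _ = make_puncta_scene(p)
        ps = detect_puncta(clahe(raster), mask, max_area_px=2)
        assert len(ps) == 0

    def test_area_filters_satisfied_exactly(self):
        p = PunctaSceneParams(n_puncta=10, noise_sigma=80.0,
                              peak_intensity=400.0, seed=3)
        raster, mask, _ = make_puncta_scene(p)
        ps = detect_puncta(clahe(raster), mask, min_area_px=4, max_area_px=200)
        assert all(4 <= q.area_px <= 200 for q in ps.puncta)

    def test_count_invariant_under_scaling(self):
        p = PunctaSceneParams(n_puncta=9, noise_sigma=60.0,
                              peak_intensity=400.0, seed=5)
        raster, mask, _ = make_puncta_scene(p)
        n1 = len(detect_puncta(clahe(raster), mask))
        n2 = len(detect_puncta(clahe(raster.rescaled(10.0)), mask))
        assert n1 == n2

    def test_degrades_monotonically_with_noise(self):
        # detection F-score should not improve as noise grows
        def f_score(sigma):
            hits = 0
            total = 0
            for seed in range(3):
                p = PunctaSceneParams(n_puncta=10, noise_sigma=sigma,
                                      peak_intensity=500.0, seed=seed)
                raster, mask, truth = make_puncta_scene(p)
                ps = detect_puncta(clahe(raster), mask)
                total += 10 + len(ps)
                if len(ps):
                    d = cdist(ps.centroids, truth.centers)
                    hits += 2 * (d.min(axis=1) <= 2.0).sum()
            return hits / total

        scores = [f_score(s) for s in (50.0, 150.0, 400.0)]
        assert scores[0] >= scores[1] >= scores[2] - 0.05
        assert scores[0] == 1.0


class TestScoring:
    def _set(self, areas):
        puncta = [
            Puncta(centroid=(1.0, 1.0), area_px=a, area_um2=float(a),
                   mean_intensity=1.0, peak_log=1.0)
            for a in areas
        ]
        return PunctaSet(puncta, None)

    def test_fold_identity(self):
        s = [self._set([10, 10])]
        assert adhesion_area_fold(s, s) == pytest.approx(1.0)

    def test_fold_simple(self):
        assert adhesion_area_fold(
            [self._set([10, 10])], [self._set([5, 5])]
        ) == pytest.approx(2.0)

    def test_fold_from_truth_radii(self):
        # brute force: fixed radii r and 2r -> area fold exactly 4
        from rhoquant.scene_sim import PunctaSceneParams, make_puncta_scene

        _, _, t1 = make_puncta_scene(PunctaSceneParams(n_puncta=5, radius_px=(3, 3), seed=1))
        _, _, t2 = make_puncta_scene(PunctaSceneParams(n_puncta=5, radius_px=(6, 6),
                                                       min_separation_px=36, seed=2))
        assert t2.areas_px.mean() / t1.areas_px.mean() == pytest.approx(4.0)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            adhesion_area_fold([self._set([10])], [self._set([])])

    def test_invadopodia_counts(self):
        sets = [self._set([1] * 3), self._set([1] * 5), self._set([1] * 7)]
        counts, mean = invadopodia_count(sets)
        assert counts == [3, 5, 7]
        assert mean == pytest.approx(5.0)

    def test_invadopodia_empty(self):
        counts, mean = invadopodia_count([self._set([]), self._set([])])
        assert mean == 0.0

    def test_mean_count_recovered_on_scenes(self):
        sets = []
        for seed in range(5):
            p = PunctaSceneParams(n_puncta=6, noise_sigma=100.0,
                                  peak_intensity=500.0, seed=seed)
            raster, mask, _ = make_puncta_scene(p)
            sets.append(detect_puncta(clahe(raster), mask))
        _, mean = invadopodia_count(sets)
        assert mean == pytest.approx(6.0, rel=0.05)


class TestLineProfile:
    def test_constant_flat(self):
        r = Raster(np.full((32, 32), 17.0))
        prof = line_profile([r], (5.0, 5.0), (25.0, 25.0))
        np.testing.assert_allclose(prof["channel_0"], 17.0)

    def test_spot_maximum_at_projected_center(self):
        raster = _spot_image(radius=3.0, shape=(64, 64))
        prof = line_profile([raster], (32.0, 5.0), (32.0, 58.0), sampling_px=0.5)
        d_at_max = prof["distance_px"][prof["channel_0"].idxmax()]
        assert d_at_max == pytest.approx(32.0 - 5.0, abs=0.5)

    def test_reversal_reverses(self):
        r = Raster(np.tile(np.arange(32, dtype=float), (32, 1)))
        f = line_profile([r], (16.0, 2.0), (16.0, 30.0))
        b = line_profile([r], (16.0, 30.0), (16.0, 2.0))
        np.testing.assert_allclose(
            f["channel_0"].to_numpy(), b["channel_0"].to_numpy()[::-1], atol=1e-9
        )

    def test_endpoint_outside_rejected(self):
        r = Raster(np.ones((16, 16)))
        with pytest.raises(ValueError, match="outside"):
            line_profile([r], (0.0, 0.0), (20.0, 5.0))

    def test_multichannel_columns(self):
        r1, r2 = Raster(np.ones((16, 16))), Raster(np.full((16, 16), 2.0))
        prof = line_profile([r1, r2], (2.0, 2.0), (12.0, 12.0))
        assert set(prof.columns) == {"distance_px", "channel_0", "channel_1"}
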