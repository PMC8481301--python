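"""Ventilation indices: breath segmentation, tidal images, linearity, GI,
CoV, RVD-SD, regional fractions, and ground-truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eitvent as ev
from eitvent.greit import normalize_difference, reconstruct
from eitvent.ventilation import (
    AnalysisError,
    BreathSegmentation,
    GlobalCurve,
    LungROI,
    TidalImage,
    center_of_ventilation,
    detect_breaths,
    gi_index,
    linearity,
    lung_roi,
    normalize_to_volume,
    regional_fractions,
    rvd_sd,
    tidal_image,
)


def _curve(values, rate=10.0):
    values = np.asarray(values, dtype=float)
    return GlobalCurve(values=values, timestamps=np.arange(len(values)) / rate)


def _tv(image, mask=None):
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    return TidalImage(image=image, breath_id=0, mask=mask)


class TestDetectBreaths:
    def test_sinusoid_yields_one_max_per_period(self):
        t = np.linspace(0, 4, 400, endpoint=False)
        seg = detect_breaths(_curve(np.sin(2 * np.pi * t)))
        assert len(seg.end_inspiration) == 4
        assert len(seg.end_expiration) in (4, 5)

    def test_constant_curve_raises(self):
        with pytest.raises(AnalysisError, match="flat"):
            detect_breaths(_curve(np.ones(50)))

    def test_svc_segment_brackets_generated_interval(self, sim_symmetric,
                                                     greit2):
        seq = sim_symmetric.noisy_frames(ev.NoiseModel(relative_noise=0.0))
        gt = sim_symmetric.ground_truth()
        dv = normalize_difference(seq.frames, 0, timestamps=seq.timestamps)
        curve = GlobalCurve.from_images(reconstruct(greit2, dv))
        seg = detect_breaths(curve)
        assert abs(seg.svc_start - gt.svc_start_frame) <= 2
        assert abs(seg.svc_peak - gt.svc_peak_frame) <= 2


class TestTidalImage:
    def test_equal_frames_give_zero_image(self, greit2, rng):
        d = rng.normal(0, 1e-3, (3, 208))
        imgs = reconstruct(greit2, ev.DifferenceData(d, 0))
        ti = tidal_image(imgs, 1, 1)
        np.testing.assert_array_equal(ti.image, 0.0)

    def test_symmetric_phantom_tidal_image_mirror_symmetric(
            self, sim_symmetric, greit2):
        seq = sim_symmetric.noisy_frames(ev.NoiseModel(relative_noise=0.0))
        gt = sim_symmetric.ground_truth()
        dv = normalize_difference(seq.frames, 0, timestamps=seq.timestamps)
        imgs = reconstruct(greit2, dv)
        ti = tidal_image(imgs, gt.svc_peak_frame, gt.svc_start_frame)
        flipped = ti.image[:, ::-1]
        scale = np.abs(ti.image).max()
        assert np.abs(ti.image - flipped).max() < 1e-6 * scale

    def test_tv_sum_equals_global_curve_difference(self, greit2, rng):
        d = rng.normal(0, 1e-3, (5, 208))
        imgs = reconstruct(greit2, ev.DifferenceData(d, 0))
        curve = GlobalCurve.from_images(imgs)
        ti = tidal_image(imgs, 4, 2)
        assert ti.image.sum() == pytest.approx(curve.values[4] - curve.values[2],
                                               rel=1e-12)

    def test_out_of_range_index_rejected(self, greit2):
        imgs = reconstruct(greit2, ev.DifferenceData(np.zeros((2, 208)), 0))
        with pytest.raises(IndexError):
            tidal_image(imgs, 5, 0)


class TestNormalizeToVolume:
    def test_unit_factor_when_volumes_match(self):
        vals, factor = normalize_to_volume(np.array([500.0]), 4000.0, 4000.0)
        assert factor == 1.0

    def test_gi_unchanged_by_normalisation(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        tv = _tv(img)
        roi = LungROI(mask=np.ones((2, 2), dtype=bool), threshold_fraction=0.2)
        before = gi_index(tv, roi)
        scaled, _ = normalize_to_volume(tv, 4000.0, 250.0)
        assert gi_index(scaled, roi) == before

    def test_factor_application(self):
        vals, factor = normalize_to_volume(np.array([500.0]), 4000.0, 5000.0)
        assert factor == pytest.approx(0.8)
        assert vals[0] == pytest.approx(400.0)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_volume(np.array([1.0]), 0.0, 1.0)
        with pytest.raises(ValueError):
            normalize_to_volume(np.array([1.0]), 1.0, -2.0)


class TestLinearity:
    def test_affine_impedance_volume_relation_gives_r_one(self):
        t = np.linspace(0, 10, 101)
        vol = np.sin(2 * np.pi * t / 10) + 1
        curve = GlobalCurve(values=3 * vol + 1, timestamps=t)
        spiro = ev.SpirometryTrace(timestamps=t, volume=vol, sampling_rate=10.0)
        seg = BreathSegmentation(np.array([0]), np.array([50]), 0, 50, 100)
        _, r, _ = linearity(curve, spiro, seg, np.array([1.0]))
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_no_temporal_overlap_rejected(self):
        curve = _curve(np.sin(np.linspace(0, 6, 60)))
        spiro = ev.SpirometryTrace(timestamps=np.array([100.0, 101.0]),
                                   volume=np.zeros(2), sampling_rate=1.0)
        seg = BreathSegmentation(np.array([0]), np.array([30]), 0, 30, 59)
        with pytest.raises(AnalysisError, match="overlap"):
            linearity(curve, spiro, seg, np.array([1.0]))

    def test_low_noise_pipeline_correlation_at_least_099(self, sim_symmetric,
                                                         run_pipeline):
        idx = run_pipeline(sim_symmetric, noise_level=5e-4, seed=3)
        assert idx.volume_impedance_r >= 0.99

    def test_tv_svc_ratio_recovers_configured_volume_ratio(self, sim_symmetric,
                                                           run_pipeline):
        """Tidal 0.5 L against a 4 L SVC under linear coupling: the
        impedance ratio reproduces 0.125 within 0.01."""
        idx = run_pipeline(sim_symmetric, noise_level=0.0)
        assert idx.tv_svc_ratio == pytest.approx(0.125, abs=0.01)


class TestLungROI:
    def test_uniform_image_roi_is_full_mask(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        roi = lung_roi(_tv(np.ones((4, 4)), mask), 0.2)
        np.testing.assert_array_equal(roi.mask, mask)

    def test_single_hot_pixel_roi(self):
        img = np.zeros((4, 4))
        img[2, 2] = 5.0
        roi = lung_roi(_tv(img), 0.2)
        assert roi.mask.sum() == 1 and roi.mask[2, 2]

    def test_matches_brute_force_thresholding(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        tv = _tv(img)
        roi = lung_roi(tv, 0.35)
        brute = np.zeros_like(img, dtype=bool)
        for i in range(32):
            for j in range(32):
                brute[i, j] = img[i, j] >= 0.35 * img.max()
        np.testing.assert_array_equal(roi.mask, brute)

    def test_zero_image_rejected(self):
        with pytest.raises(AnalysisError):
            lung_roi(_tv(np.zeros((4, 4))), 0.2)


class TestGI:
    def test_uniform_roi_gives_zero(self):
        roi = LungROI(np.ones((2, 2), dtype=bool), 0.2)
        assert gi_index(_tv(np.full((2, 2), 5.0)), roi) == 0.0

    def test_hand_computed_example(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        roi = LungROI(np.ones((2, 2), dtype=bool), 0.2)
        # median 2.5 -> sum |dev| = 4, total = 10
        assert gi_index(_tv(img), roi) == pytest.approx(0.4)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        roi = LungROI(np.ones((2, 2), dtype=bool), 0.2)
        assert gi_index(_tv(img * scale), roi) == pytest.approx(
            gi_index(_tv(img), roi), rel=1e-12)

    def test_gi_increases_as_amplitude_concentrates(self):
        """Moving a fixed share of ROI amplitude onto one pixel raises GI."""
        roi = LungROI(np.ones((4, 4), dtype=bool), 0.2)
        base = np.full((4, 4), 1.0)
        gis = []
        for frac in (0.0, 0.3, 0.6):
            img = base * (1 - frac)
            img[0, 0] += 16 * frac  # total preserved
            gis.append(gi_index(_tv(img), roi))
        assert gis[0] < gis[1] < gis[2]


class TestCoV:
    def test_mirror_symmetric_image_gives_50_percent(self):
        img = np.ones((32, 32))
        assert center_of_ventilation(_tv(img)) == pytest.approx(50.0)

    def test_most_dorsal_row_gives_984_percent(self):
        img = np.zeros((32, 32))
        img[31] = 1.0
        assert center_of_ventilation(_tv(img)) == pytest.approx(
            100 * 31.5 / 32, abs=1e-9)

    def test_weighted_two_row_example(self):
        # rows at y=0.25 and 0.75 with weights 3 and 1 -> 37.5%
        img = np.zeros((4, 4))
        img[1] = 3.0
        img[3] = 1.0
        assert center_of_ventilation(_tv(img)) == pytest.approx(
            100 * (0.375 * 3 + 0.875 * 1) / 4)

    def test_zero_image_rejected(self):
        with pytest.raises(AnalysisError):
            center_of_ventilation(_tv(np.zeros((4, 4))))


class TestRegionalFractions:
    def test_mirror_symmetric_image_splits_evenly(self):
        img = np.ones((32, 32))
        right, _ = regional_fractions(_tv(img))
        assert right == pytest.approx(0.5)

    def test_all_ventral_amplitude(self):
        img = np.zeros((32, 32))
        img[:16] = 1.0
        _, ventral = regional_fractions(_tv(img))
        assert ventral == 1.0

    def test_configured_right_weight_recovered_noiseless(self, sim_right60,
                                                         run_pipeline):
        idx = run_pipeline(sim_right60, noise_level=0.0)
        assert idx.right_fraction == pytest.approx(0.6, abs=0.05)


class TestRVD:
    def _images(self, pixel_courses, rate=10.0):
        """Build a tiny ImageSequence from per-pixel time courses."""
        n_t = len(pixel_courses[0])
        size = 32
        imgs = np.zeros((n_t, size, size))
        mask = np.zeros((size, size), dtype=bool)
        for p, course in enumerate(pixel_courses):
            mask[10, 10 + p] = True
            imgs[:, 10, 10 + p] = course
        grid = ev.PixelGrid(size=size, mask=np.ones((size, size), dtype=bool),
                            centres=np.zeros((size * size, 2)),
                            semi_axes=(1.0, 1.0))
        seq = ev.ImageSequence(images=imgs,
                               timestamps=np.arange(n_t) / rate, grid=grid)
        return seq, LungROI(mask=mask, threshold_fraction=0.2)

    def test_identical_time_courses_give_zero_sd(self):
        ramp = np.linspace(0, 1, 11)
        seq, roi = self._images([ramp, ramp, ramp])
        seg = BreathSegmentation(np.array([0]), np.array([10]), 0, 10, 10)
        assert rvd_sd(seq, seg, roi) == pytest.approx(0.0, abs=1e-9)

    def test_two_ramps_hand_computed_sd(self):
        """Ramps reaching 40% of max at 25% and 75% of the inspiration:
        RVD values {25, 75}, population SD 25."""
        t = np.linspace(0, 1, 101)
        # piecewise-linear courses rising to 1, crossing 0.4 at t=0.25 / 0.75
        fast = np.minimum(t * (0.4 / 0.25), 0.4) + np.maximum(
            0.0, (t - 0.25) * (0.6 / 0.75))
        slow = np.minimum(t * (0.4 / 0.75), 0.4) + np.maximum(
            0.0, (t - 0.75) * (0.6 / 0.25))
        seq, roi = self._images([fast, slow], rate=100.0)
        seg = BreathSegmentation(np.array([0]), np.array([100]), 0, 100, 100)
        assert rvd_sd(seq, seg, roi) == pytest.approx(25.0, abs=0.5)

    def test_sd_increases_with_interlung_lag(self, mesh2, protocol25, greit2):
        vals = []
        for tau in (0.0, 0.2, 0.4):
            ph = ev.PhantomConfig(tau_right=tau)
            sim = ev.PhantomSimulator(ph, protocol25, mesh=mesh2)
            seq = sim.noisy_frames(ev.NoiseModel(relative_noise=0.0))
            spiro = ev.volume_waveform(protocol25)
            idx = ev.analyze_recording(seq, spiro, greit2)
            vals.append(idx.rvd_sd)
        assert vals[0] < vals[1] < vals[2]

    def test_too_short_inspiration_rejected(self):
        ramp = np.linspace(0, 1, 5)
        seq, roi = self._images([ramp])
        seg = BreathSegmentation(np.array([0]), np.array([1]), 0, 1, 1)
        with pytest.raises(AnalysisError):
            rvd_sd(seq, seg, roi)


class TestScaleInvarianceOfIndexSet:
    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_ratio_indices_invariant_under_image_scaling(self, scale):
        rng = np.random.default_rng(7)
        img = rng.uniform(0.1, 1.0, (32, 32))
        tv = _tv(img)
        tvs = _tv(img * scale)
        roi = lung_roi(tv, 0.2)
        rois = lung_roi(tvs, 0.2)
        np.testing.assert_array_equal(roi.mask, rois.mask)
        assert gi_index(tvs, rois) == pytest.approx(gi_index(tv, roi), rel=1e-9)
        assert center_of_ventilation(tvs) == pytest.approx(
            center_of_ventilation(tv), rel=1e-9)
        assert regional_fractions(tvs)[0] == pytest.approx(
            regional_fractions(tv)[0], rel=1e-9)


class TestParameterRecovery:
    def test_right_fraction_bias_small_over_20_noisy_runs(self, sim_right60,
                                                          run_pipeline):
        """At 66 dB device noise the mean recovered right fraction across
        20 seeded runs stays within 0.02 of the configured 0.6, and the
        recovered CoV within 2 points of the phantom's true centroid."""
        gt = sim_right60.ground_truth()
        rights, covs = [], []
        for seed in range(20):
            idx = run_pipeline(sim_right60, noise_level=5e-4, seed=seed)
            rights.append(idx.right_fraction)
            covs.append(idx.cov_percent)
        assert abs(np.mean(rights) - 0.6) < 0.02
        assert abs(np.mean(covs) - gt.cov_percent) < 2.0

    def test_symmetric_phantom_right_left_ratio_near_unity(self, sim_symmetric,
                                                           run_pipeline):
        idx = run_pipeline(sim_symmetric, noise_level=5e-4, seed=11)
        ratio = idx.right_fraction / (1 - idx.right_fraction)
        assert ratio == pytest.approx(1.0, abs=0.05)
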