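"""FRAP pipeline: masking, corrections, binning, gradient test, fits."""
import numpy as np
import pytest
from skimage.filters import threshold_isodata

import smtkit as sk
from smtkit.config import FrapSimConfig
from smtkit.frap import (FrapCurve, analyze_frap_movie, background_subtract,
                         diffusion_timescale, extract_frap_curve,
                         fit_double_exp, fit_single_exp,
                         gradient_smoothing_test, log_bin_resample,
                         nuclear_mask, photobleach_correct)
from smtkit.simulate import frap_recovery_curve, simulate_frap_movie


@pytest.fixture(scope="module")
def clean_movie():
    cfg = FrapSimConfig(noise_sd=0.0, obs_bleach_rate=0.0)
    stack, ts, geom = simulate_frap_movie(cfg)
    return cfg, stack, ts, geom


class TestNuclearMask:
    def test_disk_geometry_recovered(self):
        cfg = FrapSimConfig(noise_sd=0.0)
        stack, _, _ = simulate_frap_movie(cfg)
        mask = nuclear_mask(stack)
        n = cfg.image_size
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        true_disk = ((xx - c) ** 2 + (yy - c) ** 2) <= \
            (cfg.nucleus_radius_um / cfg.pixel_size_um) ** 2
        inter = (mask & true_disk).sum()
        union = (mask | true_disk).sum()
        assert inter / union >= 0.95

    def test_isodata_two_level_image(self):
        # intermeans fixed point of {10, 100} is (10+100)/2 = 55
        img = np.full((32, 32), 10.0)
        img[8:24, 8:24] = 100.0
        thr = threshold_isodata(img)
        assert thr == pytest.approx(55.0, abs=0.5)

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            nuclear_mask(np.ones((5, 16, 16)))


class TestBackgroundSubtract:
    def test_uniform_background_removed(self, clean_movie):
        cfg, stack, ts, geom = clean_movie
        mask = nuclear_mask(stack)
        out = background_subtract(stack, mask)
        assert np.abs(out[:, ~mask]).max() < 1e-9

    def test_frame_varying_background(self):
        stack = np.zeros((3, 16, 16))
        stack[:, 5:11, 5:11] = 100.0
        stack[0] += 50.0
        stack[1] += 60.0
        stack[2] += 70.0
        mask = np.zeros((16, 16), dtype=bool)
        mask[5:11, 5:11] = True
        out = background_subtract(stack, mask)
        assert np.allclose(out[:, ~mask], 0.0)
        assert np.allclose(out[:, mask], 100.0)

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError):
            background_subtract(np.ones((2, 8, 8)),
                                np.ones((8, 8), dtype=bool))


class TestPhotobleachCorrect:
    def test_exponential_decay_flattened(self):
        cfg = FrapSimConfig(noise_sd=0.0, obs_bleach_rate=0.01,
                            bleach_depth=0.5)
        stack, ts, geom = simulate_frap_movie(cfg)
        mask = nuclear_mask(stack)
        corr = photobleach_correct(background_subtract(stack, mask), mask,
                                   geom["bleach_frame"])
        sums = corr[:, mask].sum(axis=1)
        b = geom["bleach_frame"]
        assert np.allclose(sums[:b], sums[b - 1], rtol=1e-9)
        assert np.allclose(sums[b:], sums[b], rtol=1e-9)

    def test_anchor_frame_scale_is_one(self, clean_movie):
        cfg, stack, ts, geom = clean_movie
        mask = nuclear_mask(stack)
        sub = background_subtract(stack, mask)
        corr = photobleach_correct(sub, mask, geom["bleach_frame"])
        b = geom["bleach_frame"]
        assert np.allclose(corr[b - 1], sub[b - 1])
        assert np.allclose(corr[b], sub[b])


class TestCurveExtraction:
    def test_pre_bleach_normalized_to_one(self, clean_movie):
        cfg, stack, ts, geom = clean_movie
        curve = analyze_frap_movie(stack, ts, geom["spot_center_px"],
                                   geom["spot_radius_px"],
                                   geom["bleach_frame"])
        raw = extract_frap_curve(
            photobleach_correct(background_subtract(
                stack, nuclear_mask(stack)), nuclear_mask(stack),
                geom["bleach_frame"]),
            ts, geom["spot_center_px"], geom["spot_radius_px"],
            geom["bleach_frame"])
        assert np.allclose(raw.values[~raw.post], 1.0, atol=1e-9)

    def test_full_bleach_no_recovery_near_zero(self):
        cfg = FrapSimConfig(bleach_depth=1.0, a1=0.0, a2=0.0, noise_sd=0.0)
        stack, ts, geom = simulate_frap_movie(cfg)
        mask = nuclear_mask(stack)
        curve = extract_frap_curve(
            photobleach_correct(background_subtract(stack, mask), mask,
                                geom["bleach_frame"]),
            ts, geom["spot_center_px"], geom["spot_radius_px"],
            geom["bleach_frame"])
        assert np.abs(curve.values[curve.post]).max() < 1e-9

    def test_round_trip_matches_ground_truth(self, clean_movie):
        cfg, stack, ts, geom = clean_movie
        curve = analyze_frap_movie(stack, ts, geom["spot_center_px"],
                                   geom["spot_radius_px"],
                                   geom["bleach_frame"])
        truth = frap_recovery_curve(cfg, curve.times)
        assert np.abs(curve.recovery - truth).max() < 1e-3


class TestLogBinning:
    def make_curve(self, t, v, f0=0.2):
        return FrapCurve(times=t, values=v, f0=f0)

    def test_constant_curve_binned_constant(self):
        t = np.linspace(0.02, 100, 1000)
        curve = self.make_curve(t, np.full(1000, 0.7))
        binned = log_bin_resample(curve)
        assert np.allclose(binned.values, 0.7)
        assert len(binned.times) <= 100
        assert np.all(np.diff(binned.times) > 0)

    def test_sparse_samples_pass_through(self):
        t = np.logspace(-1.5, 1.5, 20)
        v = np.linspace(0.2, 0.9, 20)
        binned = log_bin_resample(self.make_curve(t, v))
        assert len(binned.times) == 20
        assert np.allclose(np.sort(binned.values), np.sort(v))

    def test_binned_values_within_raw_range(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0.02, 60, 500))
        v = rng.uniform(0.2, 0.9, 500)
        binned = log_bin_resample(self.make_curve(t, v))
        assert binned.values.min() >= v.min() - 1e-12
        assert binned.values.max() <= v.max() + 1e-12

    def test_all_samples_before_tmin_rejected(self):
        with pytest.raises(ValueError):
            log_bin_resample(self.make_curve(np.array([0.001]),
                                             np.array([0.5])))


class TestGradientSmoothing:
    def test_reaction_recovery_not_flagged(self):
        cfg = FrapSimConfig(mode="reaction", noise_sd=0.0)
        stack, ts, geom = simulate_frap_movie(cfg)
        mask = nuclear_mask(stack)
        corr = photobleach_correct(background_subtract(stack, mask), mask,
                                   geom["bleach_frame"])
        _, flag = gradient_smoothing_test(corr, ts, geom["spot_center_px"],
                                          geom["bleach_frame"])
        assert flag is False

    def test_diffusive_recovery_flagged(self):
        cfg = FrapSimConfig(mode="diffusion", noise_sd=0.0)
        stack, ts, geom = simulate_frap_movie(cfg)
        mask = nuclear_mask(stack)
        corr = photobleach_correct(background_subtract(stack, mask), mask,
                                   geom["bleach_frame"])
        _, flag = gradient_smoothing_test(corr, ts, geom["spot_center_px"],
                                          geom["bleach_frame"])
        assert flag is True

    def test_single_frame_flag_undefined(self):
        cfg = FrapSimConfig(noise_sd=0.0)
        stack, ts, geom = simulate_frap_movie(cfg)
        profiles, flag = gradient_smoothing_test(
            stack, ts, geom["spot_center_px"], geom["bleach_frame"],
            n_frames=1)
        assert flag is None and len(profiles) == 1


class TestDiffusionTimescale:
    def test_spot_crossing_time(self):
        # 0.75 µm spot, D = 2 µm²/s: r²/(4D) ≈ 70 ms
        assert diffusion_timescale(0.75, 2.0) == pytest.approx(0.0703,
                                                               abs=5e-4)

    def test_quadratic_in_radius(self):
        assert diffusion_timescale(1.5, 2.0) == \
            pytest.approx(4 * diffusion_timescale(0.75, 2.0))

    def test_vanishes_for_fast_diffusion(self):
        assert diffusion_timescale(0.75, 1e9) < 1e-9


class TestExponentialFits:
    @staticmethod
    def binned_from(t, y, f0=0.2):
        return FrapCurve(times=t, values=f0 + (1 - f0) * y, f0=f0,
                         binned=True)

    def test_single_exp_self_consistency(self):
        t = np.logspace(-2, 2, 60)
        y = 0.8 * (1 - np.exp(-t / 5.0))
        fit = fit_single_exp(self.binned_from(t, y))
        assert fit.params["A"] == pytest.approx(0.8, abs=1e-4)
        assert fit.params["tau"] == pytest.approx(5.0, rel=1e-4)

    def test_double_exp_self_consistency_and_model_selection(self):
        t = np.logspace(-2, 2.3, 80)
        y = 0.5 * (1 - np.exp(-t / 2.0)) + 0.3 * (1 - np.exp(-t / 30.0))
        curve = self.binned_from(t, y)
        fd = fit_double_exp(curve)
        fs = fit_single_exp(curve)
        assert fd.params["A1"] == pytest.approx(0.5, abs=1e-3)
        assert fd.params["tau1"] == pytest.approx(2.0, rel=1e-3)
        assert fd.params["A2"] == pytest.approx(0.3, abs=1e-3)
        assert fd.params["tau2"] == pytest.approx(30.0, rel=1e-3)
        assert fd.params["tau1"] <= fd.params["tau2"]
        assert fs.rss > fd.rss

    def test_amplitude_sum_constraint_saturates(self):
        # data generated beyond full recovery: fit pins A1+A2 at 1
        t = np.logspace(-2, 2.3, 80)
        y = 0.7 * (1 - np.exp(-t / 2.0)) + 0.5 * (1 - np.exp(-t / 30.0))
        fit = fit_double_exp(self.binned_from(t, y))
        assert fit.params["A1"] + fit.params["A2"] == pytest.approx(1.0,
                                                                    abs=1e-6)

    def test_unbinned_curve_rejected_by_default(self):
        t = np.linspace(0.02, 50, 200)
        curve = FrapCurve(times=t, values=np.full(200, 0.5), f0=0.2,
                          binned=False)
        with pytest.raises(ValueError):
            fit_single_exp(curve)

    def test_end_to_end_noisy_movie(self):
        cfg = FrapSimConfig(noise_sd=0.02, obs_bleach_rate=0.002, seed=77)
        stack, ts, geom = simulate_frap_movie(cfg)
        curve = analyze_frap_movie(stack, ts, geom["spot_center_px"],
                                   geom["spot_radius_px"],
                                   geom["bleach_frame"])
        fit = fit_double_exp(curve)
        assert fit.params["tau1"] == pytest.approx(cfg.tau1_s, rel=0.2)
        assert fit.params["tau2"] == pytest.approx(cfg.tau2_s, rel=0.2)
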