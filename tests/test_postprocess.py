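"""Masks, the mutual artifact-correction pipeline, map statistics, SNR,
profile FWHM and Fourier ring correlation."""

import warnings

import numpy as np
import pytest

import imflux as ix
from imflux.postprocess import (
    InsufficientPairsError,
    ProfileFitError,
    RegistrationError,
    UndefinedSNRError,
)


class TestTIRFMask:
    def test_threshold_value(self):
        img = np.array([[1.0, 5.0], [10.0, 3.0]])
        np.testing.assert_array_equal(ix.tirf_mask(img, 5.0),
                                      [[False, True], [True, False]])

    def test_min_threshold_gives_all_true(self):
        img = np.arange(9.0).reshape(3, 3)
        assert ix.tirf_mask(img, 0.0).all()

    def test_otsu_lands_between_modes(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(100, 5, 500),
                              rng.normal(400, 20, 500)]).reshape(25, 40)
        mask = ix.tirf_mask(img, "otsu")
        # Otsu's threshold must land in the gap between the two modes
        assert abs(mask.sum() - (img > 250).sum()) <= 5

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            mask = ix.tirf_mask(np.ones((4, 4)), 10.0)
        assert not mask.any()


class TestDThreshold:
    def _map(self, values):
        v = np.asarray(values, dtype=float)
        return ix.ParameterMap(v, np.isfinite(v), "D", "um^2/s")

    def test_bimodal_valley_between_modes(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([
            10 ** rng.normal(np.log10(0.05), 0.15, 300),
            10 ** rng.normal(np.log10(0.8), 0.15, 300)]).reshape(30, 20)
        thr, info = ix.d_histogram_threshold(self._map(vals))
        assert 0.05 < thr < 0.8
        assert not info["fallback"]

    def test_unimodal_falls_back(self):
        rng = np.random.default_rng(3)
        vals = 10 ** rng.normal(0.0, 0.1, (20, 20))
        with pytest.warns(UserWarning, match="unimodal"):
            thr, info = ix.d_histogram_threshold(self._map(vals))
        assert thr == pytest.approx(0.2)
        assert info["fallback"]

    def test_two_delta_modes_threshold_strictly_between(self):
        vals = np.concatenate([np.full(200, 0.05), np.full(200, 0.8)])
        rng = np.random.default_rng(0)
        vals = vals * (1 + 0.02 * rng.normal(size=400))
        thr, _ = ix.d_histogram_threshold(self._map(vals.reshape(20, 20)))
        assert 0.06 < thr < 0.75

    def test_too_few_pixels_raise(self):
        with pytest.raises(ValueError):
            ix.d_histogram_threshold(self._map(np.full((5, 5), 0.5)))


class TestCorrectSuperres:
    def _setup(self):
        rng = np.random.default_rng(4)
        sr = ix.SuperResImage(rng.random((20, 20)), magnification=2)
        tirf = np.zeros((10, 10), bool)
        tirf[2:8, 2:8] = True
        dvals = np.full((10, 10), 1.0)
        dvals[5:8, 5:8] = 0.05
        dmap = ix.ParameterMap(dvals, np.ones((10, 10), bool), "D")
        return sr, tirf, dmap

    def test_all_true_masks_identity(self):
        sr, _, dmap = self._setup()
        res = ix.correct_superres(sr, np.ones((10, 10), bool), dmap, 0.0)
        np.testing.assert_array_equal(res.corrected_superres.image, sr.image)

    def test_inclusion_chain_and_zero_outside(self):
        sr, tirf, dmap = self._setup()
        res = ix.correct_superres(sr, tirf, dmap, 0.2)
        assert np.all(res.d_filtered_mask <= tirf)  # subset
        up = ix.upsample_mask(res.d_filtered_mask, 2)
        assert not res.corrected_superres.image[~up].any()
        assert res.d_summary_after["n"] <= res.d_summary_before["n"]

    def test_idempotent(self):
        sr, tirf, dmap = self._setup()
        res1 = ix.correct_superres(sr, tirf, dmap, 0.2)
        res2 = ix.correct_superres(res1.corrected_superres, tirf, dmap, 0.2)
        np.testing.assert_array_equal(res1.corrected_superres.image,
                                      res2.corrected_superres.image)

    def test_grid_mismatch_raises(self):
        sr, tirf, dmap = self._setup()
        bad = ix.SuperResImage(np.ones((21, 20)), magnification=2)
        with pytest.raises(RegistrationError):
            ix.correct_superres(bad, tirf, dmap, 0.2)

    def test_low_snr_warns(self):
        sr, tirf, dmap = self._setup()
        with pytest.warns(UserWarning, match="SNR"):
            ix.correct_superres(sr, tirf, dmap, 0.2, snr_value=1.5)

    def test_pipeline_removes_artifact_and_keeps_fibre(
            self, fibre_blob_stack, fibre_maps, pipeline_result):
        _, truth, _ = fibre_blob_stack
        _, sr = fibre_maps
        res, thr, info, mask = pipeline_result
        up_fibre = ix.upsample_mask(truth.fibre_mask, 5)
        nz = sr.image > 0
        out = res.corrected_superres.image
        removal = 1 - ((out > 0) & ~up_fibre).sum() / (nz & ~up_fibre).sum()
        retention = ((out > 0) & up_fibre).sum() / (nz & up_fibre).sum()
        assert removal >= 0.95
        assert retention >= 0.95
        assert res.d_summary_after["cov"] < res.d_summary_before["cov"]
        assert 0.05 < thr < 1.0


class TestMapCorrelation:
    def test_proportional_maps_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        a = rng.random((20, 20)) + 0.1
        r, n, hist = ix.map_correlation(a, 2 * a)
        assert r == pytest.approx(1.0)
        assert n == 400
        assert hist.sum() == 400

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = rng.random((100, 100))
        b = rng.random((100, 100))
        r, n, _ = ix.map_correlation(a, b)
        assert abs(r) < 0.05

    def test_affine_invariance_linear_power_invariance_log(self):
        rng = np.random.default_rng(2)
        a = rng.random((30, 30)) + 0.5
        b = rng.random((30, 30)) + 0.5
        r0, _, _ = ix.map_correlation(a, b)
        r1, _, _ = ix.map_correlation(3 * a + 2, 0.5 * b - 0.1)
        assert r1 == pytest.approx(r0, abs=1e-12)
        l0, _, _ = ix.map_correlation(a, b, log_transform=True)
        l1, _, _ = ix.map_correlation(a ** 2.5, 4 * b ** 0.7,
                                      log_transform=True)
        assert l1 == pytest.approx(l0, abs=1e-12)

    def test_brightness_diffusion_anticorrelation_sign(self):
        """Brightness elevated inside slow-diffusion domains gives a
        negative log-log correlation."""
        rng = np.random.default_rng(3)
        slow = np.zeros((40, 40), bool)
        slow[10:25, 5:30] = True
        D = np.where(slow, 0.1, 1.0) * 10 ** rng.normal(0, 0.1, (40, 40))
        B = np.where(slow, 5.0, 1.0) * 10 ** rng.normal(0, 0.1, (40, 40))
        r, _, _ = ix.map_correlation(B, D, log_transform=True)
        assert r < -0.5

    def test_nonpositive_values_excluded_under_log(self):
        a = np.array([[1.0, -1.0], [2.0, 3.0]] * 6)
        b = np.ones_like(a)
        with pytest.raises(InsufficientPairsError):
            ix.map_correlation(a[:2], b[:2], log_transform=True)
        r, n, _ = ix.map_correlation(a, b + a, log_transform=True)
        assert n == a.size - 6  # the negative entries dropped

    def test_dimension_mismatch_raises(self):
        with pytest.raises(RegistrationError):
            ix.map_correlation(np.ones((4, 4)), np.ones((5, 5)))


class TestSNR:
    def test_arithmetic(self):
        rng = np.random.default_rng(0)
        data = np.full((2000, 10, 10), 100.0)
        sig = np.zeros((10, 10), bool)
        sig[:5] = True
        data[:, sig] = rng.normal(110, 5, (2000, 50))
        data = data.clip(0)
        res = ix.snr(ix.ImageStack(data, 0.002), sig, ~sig)
        assert res.snr == pytest.approx(2.0, rel=0.05)

    def test_identical_statistics_give_zero(self):
        rng = np.random.default_rng(1)
        data = rng.normal(100, 5, (500, 8, 8)).clip(0)
        sig = np.zeros((8, 8), bool)
        sig[:4] = True
        res = ix.snr(ix.ImageStack(data, 0.002), sig, ~sig)
        assert abs(res.snr) < 0.05

    def test_zero_sd_is_undefined(self):
        data = np.full((100, 4, 4), 50.0)
        sig = np.zeros((4, 4), bool)
        sig[:2] = True
        with pytest.raises(UndefinedSNRError):
            ix.snr(ix.ImageStack(data, 0.002), sig, ~sig)

    def test_overlapping_regions_rejected(self):
        rng = np.random.default_rng(2)
        stack = ix.ImageStack(rng.poisson(100, (50, 4, 4)), 0.002)
        sig = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            ix.snr(stack, sig, sig)

    def test_em_gain_beats_read_noise_limited_detection(self):
        """At matched low photon flux, the EM register lifts the signal far
        above the read noise, so the EMCCD-like SNR exceeds the unity-gain
        (sCMOS-like) SNR."""
        results = {}
        for name, det in (
                ("emccd", ix.Detector(offset=100, read_noise_sd=10,
                                      em_gain=300, use_em_gamma=True)),
                ("low_gain", ix.Detector(offset=100, read_noise_sd=10,
                                         em_gain=1))):
            cfg = ix.SimulationConfig(
                seed=13, shape=(16, 16), n_frames=1500,
                species=[ix.Species(d_um2_s=1.0, density_per_um2=0.0,
                                    n_molecules=30, counts_per_fluorophore=3.0,
                                    confine_center_um=(1.9, 1.9),
                                    confine_radius_um=1.4)],
                detector=det)
            stack, _ = ix.simulate_stack(cfg)
            sig = np.zeros((16, 16), bool)
            sig[4:12, 4:12] = True
            bgr = np.zeros((16, 16), bool)
            bgr[0:3, :] = True
            results[name] = ix.snr(stack, sig, bgr).snr
        assert results["emccd"] > results["low_gain"]


class TestProfileFWHM:
    def test_gaussian_ridge_closed_form(self):
        yy, xx = np.indices((40, 40))
        d_px = 100 / 50  # 100 nm SD at 50 nm pixels
        img = 10 + 90 * np.exp(-((xx - 20) ** 2) / (2 * d_px ** 2))
        fit = ix.profile_fwhm(img, (20, 2), (20, 38), pixel_size_nm=50)
        assert fit.fwhm == pytest.approx(235.5, abs=0.5)
        assert fit.width == pytest.approx(100.0, rel=1e-3)

    def test_flat_profile_raises(self):
        with pytest.raises(ProfileFitError):
            ix.profile_fwhm(np.full((20, 20), 7.0), (10, 2), (10, 18))

    def test_short_line_rejected(self):
        with pytest.raises(ValueError):
            ix.profile_fwhm(np.ones((20, 20)), (0, 0), (0, 2), n_samples=3)


class TestFRC:
    def test_identical_images_pixel_limited(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        res = ix.frc_curve(img, img, 50.0)
        assert res.status == "pixel_limited"
        np.testing.assert_allclose(res.frc, 1.0, atol=1e-9)
        assert res.resolution_nm == pytest.approx(100.0)

    def test_independent_noise_below_support(self):
        rng = np.random.default_rng(6)
        res = ix.frc_curve(rng.normal(size=(64, 64)),
                           rng.normal(size=(64, 64)), 50.0)
        assert res.status == "below_support"
        assert res.resolution_nm is None
        assert np.abs(res.frc).mean() < 0.2

    def test_fibre_stack_resolution_below_diffraction_limit(
            self, fibre_blob_stack):
        stack, _, _ = fibre_blob_stack
        res = ix.frc_resolution(stack)
        assert res.status in ("ok", "pixel_limited")
        # PSF FWHM of the simulated optics = 2 sqrt(ln 2)/2 * 364 * 2 ≈ 428 nm
        assert res.resolution_nm < 428.0
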