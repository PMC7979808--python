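"""Radiality transform, TRAC2 compression and SOFI cumulants."""

import numpy as np
import pytest

import imflux as ix
from imflux.superres import InsufficientFramesError, SRRFParams


def gaussian_spot(shape, cy, cx, sigma=1.0, amp=100.0):
    yy, xx = np.indices(shape)
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


def subpixel_centre(rad, M=5):
    i, j = np.unravel_index(np.argmax(rad), rad.shape)
    return (i + 0.5) / M - 0.5, (j + 0.5) / M - 0.5


class TestRadiality:
    def test_symmetric_spot_peak_within_one_subpixel(self):
        img = gaussian_spot((15, 15), 7.3, 6.8)
        rad = ix.radiality_frame(img, SRRFParams())
        cy, cx = subpixel_centre(rad)
        assert abs(cy - 7.3) <= 0.2  # one sub-pixel at M = 5
        assert abs(cx - 6.8) <= 0.2

    def test_uniform_gradient_gives_zero_radiality(self):
        ramp = np.tile(np.arange(15.0), (15, 1)) * 3 + 5
        rad = ix.radiality_frame(ramp, SRRFParams(intensity_weighting=False))
        assert rad.max() < 1e-9

    def test_all_zero_frame_gives_zero_radiality(self):
        rad = ix.radiality_frame(np.zeros((8, 8)), SRRFParams())
        assert not rad.any()

    def test_rotation_equivariance(self):
        img = gaussian_spot((17, 17), 8.0, 8.0, sigma=1.3)
        rad = ix.radiality_frame(img, SRRFParams(intensity_weighting=False))
        rad_rot = ix.radiality_frame(np.rot90(img).copy(),
                                     SRRFParams(intensity_weighting=False))
        # centred symmetric spot: rotating the image rotates the map
        diff = np.abs(np.rot90(rad) - rad_rot)
        assert diff.max() < 0.05 * rad.max()

    def test_small_frame_rejected(self):
        with pytest.raises(ValueError):
            ix.radiality_frame(np.zeros((4, 4)), SRRFParams())

    def test_output_is_magnified_nonnegative(self):
        img = gaussian_spot((10, 12), 5, 6)
        rad = ix.radiality_frame(img, SRRFParams(magnification=5))
        assert rad.shape == (50, 60)
        assert rad.min() >= 0


class TestSRRF:
    def test_static_structure_trac2_zero_mean_mode_keeps_structure(self):
        frame = gaussian_spot((12, 12), 6, 6)
        stack = ix.ImageStack(np.repeat(frame[None], 8, axis=0), 0.2)
        sr = ix.srrf(stack, SRRFParams(temporal_bin=1, temporal_mode="TRAC2"))
        assert np.allclose(sr.image, 0.0)
        srm = ix.srrf(stack, SRRFParams(temporal_bin=1, temporal_mode="mean"))
        assert srm.image.max() > 0

    def test_single_radiality_frame_trac2_raises(self):
        frame = gaussian_spot((12, 12), 6, 6)
        stack = ix.ImageStack(frame[None], 0.2)
        with pytest.raises(InsufficientFramesError):
            ix.srrf(stack, SRRFParams(temporal_bin=1))

    def test_scale_invariance_in_normalized_mode(self):
        rng = np.random.default_rng(3)
        data = rng.poisson(100, (40, 10, 10)).astype(float)
        params = SRRFParams(temporal_bin=1, normalize_scale=True)
        a = ix.srrf(ix.ImageStack(data, 0.1), params)
        b = ix.srrf(ix.ImageStack(data * 13.7, 0.1), params)
        np.testing.assert_allclose(a.image, b.image, rtol=1e-9)

    def test_blinking_pair_resolved_below_raw_limit(self):
        """Two emitters 1.6 px apart (sigma 1 px) blink with temporal
        persistence; the raw sum shows one maximum, the TRAC2 radiality
        image shows peaks at both emitter positions."""
        rng = np.random.default_rng(7)
        T, sep = 400, 1.6
        yy, xx = np.indices((21, 21))
        g1 = np.exp(-((yy - 10) ** 2 + (xx - 10 - sep / 2) ** 2) / 2)
        g2 = np.exp(-((yy - 10) ** 2 + (xx - 10 + sep / 2) ** 2) / 2)

        def blink(T):
            s = np.zeros(T, bool)
            s[0] = True
            for t in range(1, T):
                s[t] = rng.random() < (0.85 if s[t - 1] else 0.15)
            return s

        b1, b2 = blink(T), blink(T)
        frames = np.stack([
            rng.poisson(20 + 400 * (b1[t] * g1 + b2[t] * g2))
            for t in range(T)]).astype(float)
        raw = frames.mean(axis=0)[10, :]
        n_raw = np.sum((raw[1:-1] > raw[:-2]) & (raw[1:-1] > raw[2:])
                       & (raw[1:-1] > 0.25 * raw.max()))
        assert n_raw == 1
        sr = ix.srrf(ix.ImageStack(frames, 0.2),
                     SRRFParams(temporal_bin=1, temporal_mode="TRAC2"))
        prof = sr.image[52, :]
        peaks = np.nonzero((prof[1:-1] > prof[:-2]) & (prof[1:-1] > prof[2:])
                           & (prof[1:-1] > 0.25 * prof.max()))[0] + 1
        # emitter x = 10 ± 0.8 px -> sub-pixels 48 and 56
        assert np.any(np.abs(peaks - 48) <= 1)
        assert np.any(np.abs(peaks - 56) <= 1)

    def test_trac2_contrast_beats_mean_radiality(self, fibre_blob_stack,
                                                 fibre_maps, fibre_core_mask):
        stack, _, _ = fibre_blob_stack
        _, sr = fibre_maps
        srm = ix.srrf(stack, SRRFParams(temporal_mode="mean"))
        bg = ~ix.tirf_mask(stack.mean_image(), 130.0)
        upc = ix.upsample_mask(fibre_core_mask, 5)
        upb = ix.upsample_mask(bg, 5)
        c_trac = sr.image[upc].mean() / sr.image[upb].mean()
        c_mean = srm.image[upc].mean() / srm.image[upb].mean()
        assert c_trac > c_mean

    def test_fibre_profile_narrows_at_least_twofold(self, fibre_blob_stack,
                                                    fibre_maps):
        stack, _, _ = fibre_blob_stack
        _, sr = fibre_maps
        c = 4.0 / 0.24 - 0.5
        L = 8 / np.sqrt(2)
        tirf = ix.profile_fwhm(stack.mean_image(), (c - L, c + L),
                               (c + L, c - L), 240.0)
        cs = 4.0 / 0.048 - 0.5
        Ls = L * 5
        srrf_fit = ix.profile_fwhm(sr.image, (cs - Ls, cs + Ls),
                                   (cs + Ls, cs - Ls), 48.0)
        assert srrf_fit.fwhm < tirf.fwhm / 2

    def test_crop_border_removes_ring_margin(self):
        img = np.arange(100.0 * 100).reshape(100, 100)
        sr = ix.SuperResImage(img, magnification=5, border_orig_px=2)
        cropped = ix.crop_border(sr)
        assert cropped.image.shape == (80, 80)
        np.testing.assert_array_equal(cropped.image, img[10:90, 10:90])


class TestSOFI:
    def test_gaussian_noise_has_vanishing_fourth_cumulant(self):
        rng = np.random.default_rng(0)
        data = np.abs(rng.normal(1000, 10, (2000, 8, 8)))
        stack = ix.ImageStack(data, 0.002)
        k2 = ix.sofi(stack, 2, bleach_order=0).image
        k4 = ix.sofi(stack, 4, bleach_order=0).image
        # |kappa4| of Gaussian noise is sampling noise ~ sqrt(96/T) * m2^2
        assert (k4 / k2 ** 2).mean() < 5 * np.sqrt(96 / 2000)

    def test_kappa2_equals_nb_variance_numerator(self):
        rng = np.random.default_rng(5)
        data = rng.poisson(200, (600, 6, 6)).astype(float)
        stack = ix.ImageStack(data, 0.02)
        k2 = ix.sofi(stack, 2, bleach_order=0).image
        nb = ix.nb_maps(stack, ix.DarkCalibration(0.0, 0.0), mode="variance",
                        bleach_order=0, intensity_filter=None)
        variance_numerator = nb.B.values * (stack.mean_image())
        np.testing.assert_allclose(k2, variance_numerator, rtol=5e-3)

    def test_two_state_blinking_variance(self):
        rng = np.random.default_rng(1)
        p_on, A = 0.3, 50.0
        state = rng.random(5000) < p_on
        data = np.zeros((5000, 5, 5))
        data[:, 2, 2] = A * state
        k2 = ix.sofi(ix.ImageStack(data, 0.01), 2, bleach_order=0).image
        assert k2[2, 2] == pytest.approx(p_on * (1 - p_on) * A ** 2, rel=0.05)
        assert k2[0, 0] == 0.0

    def test_order4_profile_narrower_than_order2(self, fibre_blob_stack):
        stack, _, _ = fibre_blob_stack
        binned = ix.bin_temporal(stack, 100, mode="mean")
        s2 = ix.sofi(binned, 2)
        s4 = ix.sofi(binned, 4)
        c = 4.0 / 0.24 - 0.5
        L = 8 / np.sqrt(2)
        line = ((c - L, c + L), (c + L, c - L))
        f2 = ix.profile_fwhm(s2.image, *line, 240.0)
        f4 = ix.profile_fwhm(s4.image, *line, 240.0)
        assert f4.fwhm < f2.fwhm

    def test_invalid_order_rejected(self):
        stack = ix.ImageStack(np.ones((10, 5, 5)), 0.01)
        with pytest.raises(ValueError):
            ix.sofi(stack, 3)
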