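"""Artifact correction and map-level statistics.

The mutual-correction pipeline filters a computational super-resolution
image by the dynamics measured on the very same stack: (1) a TIRF
intensity mask keeps structure-containing pixels, (2) the diffusion map is
thresholded at the valley of its (log) histogram — fast diffusion is
consistent with molecules moving on fibres, slow "diffusion" marks
stationary bright artefacts — and (3) super-resolution sub-pixels outside
the resulting mask are zeroed.  Conversely, diffusion statistics on the
fibres are reported before and after filtering.

Also here: log-log Pearson map correlation, SNR (signal/background and
on/off-fibre variants), Gaussian line-profile FWHM, and Fourier ring
correlation resolution at the 1/7 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .stack import ImageStack, ParameterMap
from .superres import SuperResImage

FRC_THRESHOLD = 1.0 / 7.0
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class RegistrationError(ValueError):
    pass


class InsufficientPairsError(ValueError):
    pass


class UndefinedSNRError(ValueError):
    pass


class ProfileFitError(RuntimeError):
    pass


def tirf_mask(mean_image: np.ndarray, threshold="otsu") -> np.ndarray:
    """Boolean mask: mean intensity ≥ threshold (value or Otsu)."""
    img = np.asarray(mean_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("mean image must be finite")
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(img))
    if threshold > img.max():
        warnings.warn("threshold above image maximum; mask is empty", stacklevel=2)
    return img >= threshold


def d_histogram_threshold(
    d_map: ParameterMap,
    mask: np.ndarray | None = None,
    bins: int = 40,
    fallback: float = 0.2,
    min_pixels: int = 100,
) -> tuple[float, dict]:
    """Diffusion threshold from the valley of the log₁₀ D histogram.

    A 40-bin histogram of log₁₀ D over valid (masked) pixels is smoothed by
    a window-3 moving average; when two or more peaks exist, the D at the
    minimum between the two largest is returned.  A unimodal histogram falls
    back to ``fallback`` (default 0.2 µm²/s) with ``info["fallback"]=True``.
    """
    ok = d_map.validity.copy()
    if mask is not None:
        ok &= mask
    vals = d_map.values[ok]
    vals = vals[vals > 0]
    if vals.size < min_pixels:
        raise ValueError(f"need >= {min_pixels} valid masked pixels, got {vals.size}")
    logd = np.log10(vals)
    hist, edges = np.histogram(logd, bins=bins)
    smooth = np.convolve(hist.astype(float), np.ones(3) / 3.0, mode="same")
    # require separated, non-trivial peaks so histogram raggedness inside one
    # mode is not mistaken for bimodality; zero-pad so modes hugging the
    # range edges still count as peaks
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = find_peaks(padded, height=0, distance=4,
                              prominence=0.1 * smooth.max())
    peaks = peaks - 1
    info = {"hist": smooth, "edges": edges, "n": int(vals.size), "fallback": False}
    if peaks.size >= 2:
        top2 = peaks[np.argsort(props["peak_heights"])[-2:]]
        lo, hi = int(top2.min()), int(top2.max())
        valley = lo + int(np.argmin(smooth[lo : hi + 1]))
        centre = 0.5 * (edges[valley] + edges[valley + 1])
        info["valley_bin"] = valley
        return float(10.0 ** centre), info
    info["fallback"] = True
    warnings.warn("unimodal D histogram; using fallback threshold", stacklevel=2)
    return float(fallback), info


def upsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour block replication: each map pixel governs its
    factor×factor sub-pixel block."""
    return np.kron(mask, np.ones((factor, factor), dtype=bool))


@dataclass
class MaskPipelineResult:
    tirf_mask: np.ndarray
    d_threshold: float
    d_filtered_mask: np.ndarray
    corrected_superres: SuperResImage
    d_summary_before: dict = field(default_factory=dict)
    d_summary_after: dict = field(default_factory=dict)


def _d_summary(dvals: np.ndarray) -> dict:
    if dvals.size == 0:
        return {"mean": np.nan, "sd": np.nan, "cov": np.nan, "n": 0}
    m = float(np.mean(dvals))
    s = float(np.std(dvals, ddof=1)) if dvals.size > 1 else 0.0
    return {"mean": m, "sd": s, "cov": s / m if m else np.nan, "n": int(dvals.size)}


def correct_superres(
    superres: SuperResImage,
    tirf_mask_map: np.ndarray,
    d_map: ParameterMap,
    d_threshold: float,
    snr_value: float | None = None,
) -> MaskPipelineResult:
    """Mutual artifact correction of a super-resolution image by dynamics.

    Zeroes super-resolution sub-pixels outside the up-sampled TIRF mask,
    builds the D-filtered mask (TIRF ∧ D ≥ threshold ∧ validity) and zeroes
    outside it as well; returns all intermediates plus on/off-fibre D
    summaries before and after filtering.
    """
    H, W = tirf_mask_map.shape
    if d_map.shape != (H, W):
        raise RegistrationError("TIRF mask and D map must share a grid")
    sh, sw = superres.image.shape
    if sh % H or sw % W or sh // H != sw // W:
        raise RegistrationError(
            f"super-res grid {superres.image.shape} is not an integer multiple "
            f"of the map grid {(H, W)}")
    factor = sh // H
    if snr_value is not None and snr_value < 3.0:
        warnings.warn(
            f"region SNR {snr_value:.2f} < 3; D-based filtering may be inefficient",
            stacklevel=2)
    masked = superres.image * upsample_mask(tirf_mask_map, factor)
    d_ok = d_map.validity & (d_map.values >= d_threshold)
    d_filtered = tirf_mask_map & d_ok
    corrected = masked * upsample_mask(d_filtered, factor)
    before = _d_summary(d_map.values[tirf_mask_map & d_map.validity])
    after = _d_summary(d_map.values[d_filtered])
    out = SuperResImage(corrected, superres.magnification, superres.pixel_size_nm,
                        superres.method + "+Dfilter", dict(superres.params),
                        superres.border_orig_px)
    return MaskPipelineResult(
        tirf_mask=tirf_mask_map.astype(bool),
        d_threshold=float(d_threshold),
        d_filtered_mask=d_filtered,
        corrected_superres=out,
        d_summary_before=before,
        d_summary_after=after,
    )


def map_correlation(
    map1: ParameterMap | np.ndarray,
    map2: ParameterMap | np.ndarray,
    log_transform: bool = False,
    hist_bins: int = 40,
) -> tuple[float, int, np.ndarray]:
    """Pearson correlation of two co-registered maps.

    Only pixels valid in both maps enter; under ``log_transform`` both
    values are log₁₀-transformed and non-positive pairs are excluded (their
    count is reported via the attribute on the returned histogram is not
    needed — excluded pairs simply reduce n).  Returns (R, n, 2-D frequency
    table).
    """
    v1, ok1 = _as_values(map1)
    v2, ok2 = _as_values(map2)
    if v1.shape != v2.shape:
        raise RegistrationError("maps must share dimensions (bin first)")
    ok = ok1 & ok2 & np.isfinite(v1) & np.isfinite(v2)
    x, y = v1[ok], v2[ok]
    if log_transform:
        pos = (x > 0) & (y > 0)
        x, y = np.log10(x[pos]), np.log10(y[pos])
    if x.size < 10:
        raise InsufficientPairsError(f"only {x.size} valid pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    hist, _, _ = np.histogram2d(x, y, bins=hist_bins)
    return r, int(x.size), hist


def _as_values(m):
    if isinstance(m, ParameterMap):
        return m.values, m.validity
    arr = np.asarray(m, dtype=float)
    return arr, np.isfinite(arr)


@dataclass
class SNRResult:
    signal_mean: float
    background_mean: float
    signal_sd: float
    snr: float


def snr(
    stack: ImageStack,
    signal_pixels: np.ndarray,
    background_pixels: np.ndarray,
) -> SNRResult:
    """SNR = (⟨I_signal⟩ − ⟨I_background⟩)/σ_signal.

    Regions are boolean masks (or index arrays) over the image; means run
    over pixels and frames, σ is the pooled SD of the signal region's
    samples.  The on/off-fibre variant is the same formula with fibre /
    off-fibre regions.
    """
    sig = stack.data[:, signal_pixels].astype(np.float64)
    bgr = stack.data[:, background_pixels].astype(np.float64)
    if sig.size == 0 or bgr.size == 0:
        raise ValueError("regions must be non-empty")
    if isinstance(signal_pixels, np.ndarray) and signal_pixels.dtype == bool \
            and np.any(signal_pixels & background_pixels):
        raise ValueError("signal and background regions must be disjoint")
    s_mean = float(sig.mean())
    b_mean = float(bgr.mean())
    s_sd = float(sig.std(ddof=1))
    if s_sd == 0:
        raise UndefinedSNRError("zero signal SD")
    return SNRResult(s_mean, b_mean, s_sd, (s_mean - b_mean) / s_sd)


@dataclass
class GaussianProfileFit:
    offset: float
    peak: float
    centre: float
    width: float  # Gaussian SD, physical units
    fwhm: float
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)


def profile_fwhm(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    pixel_size_nm: float = 1.0,
    n_samples: int | None = None,
) -> GaussianProfileFit:
    """FWHM of a Gaussian fit y = a + (b−a)·exp(−(x−c)²/(2d²)) to the
    intensity profile along a line segment ((row, col) endpoints).

    Intensities are linearly interpolated along the segment; x is in
    physical units via ``pixel_size_nm``; FWHM = 2√(2 ln 2)·d.
    """
    image = np.asarray(image, dtype=float)
    (r0, c0), (r1, c1) = start, end
    length_px = float(np.hypot(r1 - r0, c1 - c0))
    if n_samples is None:
        n_samples = max(int(np.ceil(length_px)) + 1, 5)
    if n_samples < 5:
        raise ValueError("line must span at least 5 samples")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    y = map_coordinates(image, np.stack([rows, cols]), order=1, mode="nearest")
    x = t * length_px * pixel_size_nm
    if np.ptp(y) <= 0:
        raise ProfileFitError("flat profile; Gaussian fit undefined")

    def model(x, a, b, c, d):
        return a + (b - a) * np.exp(-((x - c) ** 2) / (2.0 * d ** 2))

    a0 = float(y.min())
    b0 = float(y.max())
    c0_ = float(x[np.argmax(y)])
    d0 = max(length_px * pixel_size_nm / 10.0, 1e-6)
    try:
        popt, _ = curve_fit(
            model, x, y, p0=[a0, b0, c0_, d0],
            bounds=([-np.inf, -np.inf, x.min() - np.ptp(x), 1e-9],
                    [np.inf, np.inf, x.max() + np.ptp(x), np.ptp(x) * 10]),
            maxfev=5000)
    except RuntimeError as exc:
        raise ProfileFitError(f"Gaussian profile fit failed: {exc}") from exc
    resid = y - model(x, *popt)
    d = abs(float(popt[3]))
    return GaussianProfileFit(
        offset=float(popt[0]), peak=float(popt[1]), centre=float(popt[2]),
        width=d, fwhm=FWHM_FACTOR * d, x=x, y=y, residuals=resid)


@dataclass
class FRCResult:
    frequency_per_nm: np.ndarray
    frc: np.ndarray
    resolution_nm: float | None
    status: str  # "ok", "below_support", "pixel_limited"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_per_nm": self.frequency_per_nm,
                             "frc": self.frc})


def frc_curve(img1: np.ndarray, img2: np.ndarray, pixel_size_nm: float) -> FRCResult:
    """Fourier ring correlation of two independent reconstructions.

    FRC(q) = Re Σ_ring F₁·conj(F₂) / √(Σ|F₁|² Σ|F₂|²); the resolution is the
    inverse frequency at the first crossing of the fixed 1/7 threshold from
    low frequency.  A curve that never drops below 1/7 is pixel-limited; one
    that starts below it has no significant correlation ("below support").
    """
    a = np.asarray(img1, dtype=float)
    b = np.asarray(img2, dtype=float)
    if a.shape != b.shape:
        raise RegistrationError("images must share dimensions")
    a = a - a.mean()
    b = b - b.mean()
    F1 = np.fft.fftshift(np.fft.fft2(a))
    F2 = np.fft.fftshift(np.fft.fft2(b))
    H, W = a.shape
    yy, xx = np.indices((H, W))
    ry = (yy - H // 2) / H
    rx = (xx - W // 2) / W
    q = np.hypot(ry, rx)  # cycles per pixel
    n_rings = min(H, W) // 2
    ring = np.clip((q * 2 * n_rings).astype(int), 0, n_rings)
    num = np.bincount(ring.ravel(), (F1 * np.conj(F2)).real.ravel(), n_rings + 1)
    p1 = np.bincount(ring.ravel(), np.abs(F1).ravel() ** 2, n_rings + 1)
    p2 = np.bincount(ring.ravel(), np.abs(F2).ravel() ** 2, n_rings + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frc = num / np.sqrt(p1 * p2)
    freq_px = np.arange(n_rings + 1) / (2.0 * n_rings)  # cycles/pixel
    freq = freq_px / pixel_size_nm
    frc = frc[1:]
    freq = freq[1:]
    below = frc < FRC_THRESHOLD
    if below[0]:
        return FRCResult(freq, frc, None, "below_support")
    if not below.any():
        return FRCResult(freq, frc, float(2.0 * pixel_size_nm), "pixel_limited")
    i = int(np.argmax(below))
    # linear interpolation of the crossing
    f0, f1 = freq[i - 1], freq[i]
    y0, y1 = frc[i - 1], frc[i]
    fc = f0 + (FRC_THRESHOLD - y0) * (f1 - f0) / (y1 - y0)
    return FRCResult(freq, frc, float(1.0 / fc), "ok")


def frc_resolution(
    stack: ImageStack,
    superres_params=None,
    reconstruct=None,
) -> FRCResult:
    """Split a stack into odd/even frames, reconstruct each half and measure
    the FRC resolution.  ``reconstruct`` defaults to SRRF with
    ``superres_params``."""
    from .stack import ImageStack as _IS
    from .superres import SRRFParams, srrf

    if reconstruct is None:
        params = superres_params or SRRFParams()

        def reconstruct(s):
            return srrf(s, params)

    odd = _IS(stack.data[0::2], stack.frame_time * 2, stack.geometry, stack.bit_depth)
    even = _IS(stack.data[1::2], stack.frame_time * 2, stack.geometry, stack.bit_depth)
    r1 = reconstruct(odd)
    r2 = reconstruct(even)
    px = r1.pixel_size_nm or 1.0
    return frc_curve(r1.image, r2.image, px)
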