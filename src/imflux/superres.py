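"""Computational super-resolution from intensity fluctuations.

Two routes, both fed by the same stack the dynamics are measured from:

* a radiality transform (SRRF-style): on an M-times finer grid, gradient
  convergence toward each sub-pixel centre is scored on a ring of sample
  points; the radiality time series is compressed either by its temporal
  mean or by the order-2 temporal auto-cumulant (TRAC2),
  |⟨δR_t·δR_{t+1}⟩|, which suppresses static non-converging background;

* per-pixel temporal cumulants (SOFI): |κ₂| (the variance) or
  |κ₄| = |m₄ − 3m₂²| of the bleach-corrected trace — κ₄ vanishes for
  Gaussian noise, so higher orders sharpen blinking structures nonlinearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .correlator import bleach_correct_matrix
from .stack import ImageStack, bin_temporal


class InsufficientFramesError(ValueError):
    pass


@dataclass(frozen=True)
class SRRFParams:
    """Radiality parameters (defaults follow common practice for TIRF data:
    ring radius 0.5 px, 5× magnification, 6 axes, TRAC2 over 100-frame
    average bins)."""

    ring_radius: float = 0.5
    magnification: int = 5
    axes_in_ring: int = 6
    temporal_mode: str = "TRAC2"
    temporal_bin: int = 100
    intensity_weighting: bool = True
    interpolation_order: int = 3
    normalize_scale: bool = False  # divide out the global mean intensity

    def __post_init__(self) -> None:
        if self.magnification < 1:
            raise ValueError("magnification must be >= 1")
        if self.axes_in_ring < 2:
            raise ValueError("axes_in_ring must be >= 2")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be > 0")
        if self.temporal_mode not in ("TRAC2", "mean"):
            raise ValueError("temporal_mode must be 'TRAC2' or 'mean'")

    @property
    def border_orig_px(self) -> int:
        """Original-pixel border affected by ring sampling, recommended crop."""
        return int(math.ceil(self.ring_radius)) + 1


@dataclass
class SuperResImage:
    """A super-resolution image plus its provenance."""

    image: np.ndarray
    magnification: int
    pixel_size_nm: float | None = None
    method: str = ""
    params: dict = field(default_factory=dict)
    border_orig_px: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def radiality_frame(frame: np.ndarray, params: SRRFParams = SRRFParams()) -> np.ndarray:
    """Radiality transform of one frame on the M-times finer grid.

    For each sub-pixel centre c, 2·axes points are sampled on a ring of
    radius ``ring_radius`` (original pixels).  Each sample contributes
    sign(convergence)·(1 − d/r) where d is the perpendicular distance of the
    gradient-direction line through the sample from c; the mean over samples
    is clipped below at 0 and (by default) weighted with the interpolated
    intensity.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape[0] < 5 or frame.shape[1] < 5:
        raise ValueError("frame must be at least 5x5 pixels")
    M = params.magnification
    H, W = frame.shape
    gy, gx = np.gradient(frame)  # central differences; gy along rows

    sub = np.arange(H * M, dtype=np.float64)
    cy = (sub[: H * M] + 0.5) / M - 0.5
    cx = (np.arange(W * M, dtype=np.float64) + 0.5) / M - 0.5
    CY, CX = np.meshgrid(cy, cx, indexing="ij")

    n_samples = 2 * params.axes_in_ring
    r = params.ring_radius
    acc = np.zeros_like(CY)
    order = params.interpolation_order
    for j in range(n_samples):
        theta = 2.0 * np.pi * j / n_samples
        st, ct = np.sin(theta), np.cos(theta)
        py = CY + r * st
        px = CX + r * ct
        coords = np.stack([py.ravel(), px.ravel()])
        gxs = map_coordinates(gx, coords, order=order, mode="nearest").reshape(CY.shape)
        gys = map_coordinates(gy, coords, order=order, mode="nearest").reshape(CY.shape)
        gnorm = np.hypot(gxs, gys)
        with np.errstate(divide="ignore", invalid="ignore"):
            # distance of the gradient line through the sample from the centre
            d = r * np.abs(ct * gys - st * gxs) / gnorm
            # converging if the gradient points from the sample toward c
            conv = -(ct * gxs + st * gys)
        contrib = np.where(gnorm > 0, np.sign(conv) * (1.0 - d / r), 0.0)
        contrib = np.where(np.isfinite(contrib), contrib, 0.0)
        acc += contrib
    rad = np.clip(acc / n_samples, 0.0, None)
    if params.intensity_weighting:
        coords = np.stack([CY.ravel(), CX.ravel()])
        inten = map_coordinates(frame, coords, order=1, mode="nearest").reshape(CY.shape)
        rad = rad * np.clip(inten, 0.0, None)
    return rad


def srrf(stack: ImageStack, params: SRRFParams = SRRFParams()) -> SuperResImage:
    """Radiality super-resolution image of a stack.

    The stack is mean-binned by ``temporal_bin`` frames, each binned frame is
    radiality-transformed, and the radiality time series is compressed by
    ``temporal_mode`` (TRAC2 or mean).
    """
    nbin = min(params.temporal_bin, stack.n_frames)
    binned = bin_temporal(stack, nbin, mode="mean") if nbin > 1 else stack
    F = binned.n_frames
    if params.temporal_mode == "TRAC2" and F < 2:
        raise InsufficientFramesError("TRAC2 needs >= 2 radiality frames")
    frames = binned.data.astype(np.float64)
    if params.normalize_scale:
        scale = frames.mean()
        if scale > 0:
            frames = frames / scale
    rad = np.stack([radiality_frame(frames[t], params) for t in range(F)])
    if params.temporal_mode == "mean":
        img = rad.mean(axis=0)
    else:
        dR = rad - rad.mean(axis=0)
        img = np.abs((dR[:-1] * dR[1:]).mean(axis=0))
    px = None
    if stack.geometry is not None:
        px = stack.geometry.object_pixel_size_nm / params.magnification
    return SuperResImage(
        image=img,
        magnification=params.magnification,
        pixel_size_nm=px,
        method=f"SRRF-{params.temporal_mode}",
        params={
            "ring_radius": params.ring_radius,
            "magnification": params.magnification,
            "axes_in_ring": params.axes_in_ring,
            "temporal_mode": params.temporal_mode,
            "temporal_bin": nbin,
        },
        border_orig_px=params.border_orig_px,
    )


def sofi(stack: ImageStack, order: int = 2, bleach_order: int = 8) -> SuperResImage:
    """Per-pixel temporal-cumulant (SOFI) image of order 2 or 4 on the
    original grid; traces are bleach-corrected first."""
    if order not in (2, 4):
        raise ValueError("order must be 2 or 4")
    traces = stack.traces()
    corrected, _ = bleach_correct_matrix(traces, bleach_order)
    d = corrected - corrected.mean(axis=0)
    m2 = (d * d).mean(axis=0)
    if order == 2:
        img = np.abs(m2)
    else:
        m4 = (d ** 4).mean(axis=0)
        img = np.abs(m4 - 3.0 * m2 ** 2)
    px = stack.geometry.object_pixel_size_nm if stack.geometry is not None else None
    return SuperResImage(
        image=img.reshape(stack.height, stack.width),
        magnification=1,
        pixel_size_nm=px,
        method=f"SOFI-{order}",
        params={"order": order, "bleach_order": bleach_order},
    )


def crop_border(sr: SuperResImage, margin_orig_px: int | None = None) -> SuperResImage:
    """Crop the ring-sampling border (in original pixels) from a
    super-resolution image; the same margin should be cropped from any
    co-registered map before overlay."""
    m = sr.border_orig_px if margin_orig_px is None else margin_orig_px
    k = m * sr.magnification
    if k == 0:
        return sr
    H, W = sr.image.shape
    if 2 * k >= H or 2 * k >= W:
        raise ValueError("crop margin consumes the whole image")
    return SuperResImage(sr.image[k : H - k, k : W - k].copy(), sr.magnification,
                         sr.pixel_size_nm, sr.method, dict(sr.params), 0)
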