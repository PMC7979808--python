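"""Image-stack data model, TIFF I/O, binning and cropping.

The universal input to every analysis stage is a time-ordered stack of 2-D
intensity frames together with the acquisition geometry (object-plane pixel
size, PSF width, wavelength, NA).  All coordinates are 0-based ``(row, col)``
with y increasing downward; binning is non-overlapping and anchored at pixel
(0, 0), trailing partial blocks are dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Input file is not a readable grayscale multi-page TIFF."""


class EmptyInputError(ValueError):
    """Operation would produce or consume an empty stack."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical geometry driving all area/time conversions.

    Parameters
    ----------
    camera_pixel_size_um
        Physical camera pixel pitch in µm (e.g. 24 for a back-illuminated
        EMCCD, 11 for an sCMOS).
    magnification
        Total optical magnification; the object-plane pixel size is
        ``camera_pixel_size_um * 1000 / magnification`` nm and is always
        recomputed, never stored.
    psf_e2_radius_nm
        Lateral 1/e² radius ω_xy of the Gaussian PSF in nm.  Calibrated from
        a freely diffusing sample (see :func:`imflux.fcs.calibrate_psf`).
    emission_wavelength_nm, numerical_aperture
        Used to express the PSF as the dimensionless factor ω·NA/λ.
    binning
        Current square pixel binning applied on top of the camera pixels.
    """

    camera_pixel_size_um: float = 24.0
    magnification: float = 100.0
    psf_e2_radius_nm: float = 364.0
    emission_wavelength_nm: float = 565.0
    numerical_aperture: float = 1.49
    binning: int = 1

    def __post_init__(self) -> None:
        if self.camera_pixel_size_um <= 0 or self.magnification <= 0:
            raise ValueError("camera pixel size and magnification must be positive")
        if self.psf_e2_radius_nm <= 0:
            raise ValueError("psf_e2_radius_nm must be positive")
        if self.binning < 1 or int(self.binning) != self.binning:
            raise ValueError("binning must be an integer >= 1")

    @property
    def object_pixel_size_nm(self) -> float:
        """Object-plane size of one (binned) pixel in nm."""
        return self.camera_pixel_size_um * 1000.0 / self.magnification * self.binning

    @property
    def psf_factor(self) -> float:
        """PSF expressed as ω_xy·NA/λ (the dimensionless convention used by
        camera-FCS software)."""
        return self.psf_e2_radius_nm * self.numerical_aperture / self.emission_wavelength_nm

    @classmethod
    def with_psf_factor(cls, factor: float, **kwargs) -> "AcquisitionGeometry":
        """Build a geometry from the dimensionless PSF factor ω·NA/λ
        (e.g. 0.96 for the calibrated 565 nm channel)."""
        tmp = cls(psf_e2_radius_nm=1.0, **kwargs)
        w = factor * tmp.emission_wavelength_nm / tmp.numerical_aperture
        return dataclasses.replace(tmp, psf_e2_radius_nm=w)

    def rebinned(self, n: int) -> "AcquisitionGeometry":
        return dataclasses.replace(self, binning=self.binning * n)


@dataclass
class ImageStack:
    """A time-ordered stack of 2-D intensity frames.

    ``data`` has shape (T, H, W) and holds non-negative finite counts;
    ``frame_time`` is the time per frame in seconds.
    """

    data: np.ndarray
    frame_time: float
    geometry: AcquisitionGeometry | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be a (T, H, W) array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1 or self.data.shape[2] < 1:
            raise EmptyInputError("stack must have at least one frame and one pixel")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def pixel_trace(self, row: int, col: int) -> np.ndarray:
        return self.data[:, row, col].astype(np.float64)

    def traces(self) -> np.ndarray:
        """All pixel traces as a (T, H*W) float matrix (C pixel order)."""
        T = self.n_frames
        return self.data.reshape(T, -1).astype(np.float64)


@dataclass
class ParameterMap:
    """A per-pixel analysis result on a (possibly binned) grid.

    ``values`` must be finite wherever ``validity`` is true.  ``origin_offset``
    records the (row, col) offset of map pixel (0, 0) in the parent stack, in
    parent pixels, so that maps from cropped regions stay registered.
    """

    values: np.ndarray
    validity: np.ndarray
    name: str = ""
    units: str = ""
    binning_used: int = 1
    origin_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.values.shape != self.validity.shape:
            raise ValueError("values and validity must have the same shape")
        if not np.all(np.isfinite(self.values[self.validity])):
            raise ValueError("values must be finite wherever validity is true")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.validity]

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.values.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "value": self.values.ravel(),
                "valid": self.validity.ravel(),
            }
        )

    def write(self, path_stem: str | Path) -> None:
        """Write the map as 32-bit float TIFF plus a CSV table."""
        stem = Path(path_stem)
        out = self.values.astype(np.float32).copy()
        out[~self.validity] = np.nan
        tifffile.imwrite(str(stem.with_suffix(".tif")), out)
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False)


def read_stack(
    path: str | Path,
    frame_time: float,
    geometry: AcquisitionGeometry | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Raises :class:`FormatError` for colour or ragged-page files and
    :class:`EmptyInputError` for zero-frame files.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series
            if not series:
                raise EmptyInputError(f"{path}: no image data")
            axes = series[0].axes
            if "S" in axes or "C" in axes:
                raise FormatError(f"{path}: colour TIFF (axes {axes}); grayscale required")
            arr = series[0].asarray()
    except (tifffile.TiffFileError, OSError) as exc:  # pragma: no cover - I/O
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise EmptyInputError(f"{path}: zero frames")
    dtype = arr.dtype
    bit_depth = dtype.itemsize * 8
    return ImageStack(arr, frame_time=frame_time, geometry=geometry, bit_depth=bit_depth)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF (dtype preserved)."""
    tifffile.imwrite(str(path), stack.data)


def bin_temporal(stack: ImageStack, n: int, mode: str = "sum") -> ImageStack:
    """Non-overlapping temporal binning of ``n`` frames (sum or mean).

    Leftover frames (< n) are dropped; ``frame_time`` scales by n.  Sum mode
    preserves the total counts over the retained frames.
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be an integer >= 1")
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    T = stack.n_frames
    if n > T:
        raise EmptyInputError(f"temporal binning {n} exceeds {T} frames")
    if n == 1:
        return ImageStack(stack.data.copy(), stack.frame_time, stack.geometry, stack.bit_depth)
    T2 = T // n
    trimmed = stack.data[: T2 * n].astype(np.float64)
    binned = trimmed.reshape(T2, n, stack.height, stack.width).sum(axis=1)
    if mode == "mean":
        binned /= n
    return ImageStack(binned, stack.frame_time * n, stack.geometry, stack.bit_depth)


def bin_spatial(stack: ImageStack, n: int, mode: str = "sum") -> ImageStack:
    """Non-overlapping n×n spatial binning anchored at pixel (0, 0).

    Trailing partial rows/columns are dropped; the attached geometry's
    binning factor scales by n.
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be an integer >= 1")
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    if n > min(stack.height, stack.width):
        raise EmptyInputError(f"spatial binning {n} exceeds image size")
    if n == 1:
        return ImageStack(stack.data.copy(), stack.frame_time, stack.geometry, stack.bit_depth)
    H2, W2 = stack.height // n, stack.width // n
    trimmed = stack.data[:, : H2 * n, : W2 * n].astype(np.float64)
    binned = trimmed.reshape(stack.n_frames, H2, n, W2, n).sum(axis=(2, 4))
    if mode == "mean":
        binned /= n * n
    geom = stack.geometry.rebinned(n) if stack.geometry is not None else None
    return ImageStack(binned, stack.frame_time, geom, stack.bit_depth)


def crop(stack: ImageStack, top: int = 0, bottom: int = 0, left: int = 0, right: int = 0) -> ImageStack:
    """Crop margins (in pixels) from every frame."""
    H, W = stack.height, stack.width
    if top + bottom >= H or left + right >= W:
        raise EmptyInputError("crop margins consume the whole image")
    data = stack.data[:, top : H - bottom if bottom else H, left : W - right if right else W]
    return ImageStack(data.copy(), stack.frame_time, stack.geometry, stack.bit_depth)
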