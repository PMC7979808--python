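"""Number & Brightness maps and oligomer-fraction algebra.

Moment analysis of a (temporally binned) stack: per pixel

    N = (⟨I⟩ − offset)² / (σ² − σ₀²)        B = (σ² − σ₀²) / (⟨I⟩ − offset)

with offset and read variance σ₀² taken from a dark calibration.  Because
the raw variance carries shot noise, the default "G1" mode replaces
σ² − σ₀² with the lag-1 covariance of the fluctuations, which uncorrelated
detector noise cannot reach (the σ₀² term then drops out).  G1 requires the
molecular signal to stay correlated across one binned frame, i.e. transit
time ≫ frame time.

Oligomerization under incomplete fluorophore maturation: a subunit is
fluorescent with probability p, so a pure k-mer is 1 + (k−1)p times brighter
than a monomer (ratio of the first two factorial moments of a binomial
count).  p follows from a tandem-dimer control (r = 1 + p); a monomer–dimer
mixture with measured ratio r has dimer molecule fraction m_e = (r − 1)/p,
and two-species mixtures of any orders solve a linear equation in the
number fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .correlator import bleach_correct_matrix
from .stack import ImageStack, ParameterMap


class CalibrationMismatchError(ValueError):
    pass


class ModelViolationError(ValueError):
    pass


class InfeasibleMixtureError(ValueError):
    pass


@dataclass
class DarkCalibration:
    """Detector offset and read variance, per pixel or global scalars."""

    offset: np.ndarray | float
    read_variance: np.ndarray | float

    @classmethod
    def from_stack(cls, dark: ImageStack, per_pixel: bool = False) -> "DarkCalibration":
        data = dark.data.astype(np.float64)
        if per_pixel:
            return cls(data.mean(axis=0), data.var(axis=0, ddof=1))
        return cls(float(data.mean()), float(data.var(ddof=1)))

    def for_shape(self, shape) -> tuple[np.ndarray, np.ndarray]:
        off = np.broadcast_to(np.asarray(self.offset, dtype=float), shape)
        var = np.broadcast_to(np.asarray(self.read_variance, dtype=float), shape)
        if np.any(np.asarray(var) < 0):
            raise CalibrationMismatchError("read variance must be >= 0")
        return off, var


@dataclass
class NBResult:
    N: ParameterMap
    B: ParameterMap
    mean_intensity: np.ndarray
    mode: str
    intensity_filter: tuple[float, float]


def nb_maps(
    stack: ImageStack,
    dark: DarkCalibration,
    mode: str = "G1",
    bleach_order: int = 8,
    intensity_filter: tuple[float, float] | str | None = "otsu",
) -> NBResult:
    """Per-pixel apparent number and brightness maps.

    ``stack`` should already be temporally binned to the N&B exposure
    (typically 10 × sum-binned 2 ms frames → 20 ms).  ``intensity_filter``
    removes background pixels on the mean image: a (lo, hi) range in counts,
    the string ``"otsu"`` (lower bound from Otsu's threshold), or None.
    """
    if mode not in ("variance", "G1"):
        raise ValueError("mode must be 'variance' or 'G1'")
    traces = stack.traces()
    H, W = stack.height, stack.width
    try:
        off, rvar = dark.for_shape((H, W))
    except ValueError as exc:
        raise CalibrationMismatchError(str(exc)) from exc
    off = off.reshape(-1)
    rvar = rvar.reshape(-1)

    mean_raw = traces.mean(axis=0)
    corrected, ok = bleach_correct_matrix(traces, bleach_order)
    d = corrected - corrected.mean(axis=0)
    if mode == "variance":
        num = (d * d).sum(axis=0) / (d.shape[0] - 1) - rvar
    else:
        num = (d[:-1] * d[1:]).sum(axis=0) / (d.shape[0] - 1)

    denom = mean_raw - off
    if intensity_filter is None:
        lo, hi = -np.inf, np.inf
    elif intensity_filter == "otsu":
        from skimage.filters import threshold_otsu

        lo, hi = float(threshold_otsu(mean_raw.reshape(H, W))), np.inf
    else:
        lo, hi = intensity_filter

    in_range = (mean_raw >= lo) & (mean_raw <= hi)
    # a pixel only carries signal when its mean exceeds the offset by more
    # than the standard error a pure dark trace would show
    floor = 5.0 * np.sqrt(np.maximum(rvar, 1e-12) / traces.shape[0])
    valid = ok & (denom > floor) & in_range & (num != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        N = np.square(denom) / num
        B = num / denom
    N[~valid] = np.nan
    B[~valid] = np.nan
    kw = dict(binning_used=stack.geometry.binning if stack.geometry else 1)
    return NBResult(
        N=ParameterMap(N.reshape(H, W), valid.reshape(H, W), "N", "particles", **kw),
        B=ParameterMap(B.reshape(H, W), valid.reshape(H, W), "B", "counts/molecule/frame", **kw),
        mean_intensity=mean_raw.reshape(H, W),
        mode=mode,
        intensity_filter=(float(lo), float(hi)),
    )


def kmer_brightness_ratio(k: int, p: float) -> float:
    """Apparent brightness of a pure k-mer relative to a monomer when each
    subunit is fluorescent with probability p: 1 + (k−1)p (= ⟨q²⟩/⟨q⟩ ÷ 1
    for q ~ Binomial(k, p))."""
    return 1.0 + (k - 1) * p


def fluorescent_fraction(r_dimer_monomer: float, se_r: float | None = None):
    """Fluorescent probability p from a tandem-dimer / monomer brightness
    ratio: p = r − 1 (binomial model).  Returns p, or (p, SE) when an SE for
    r is given."""
    r = float(r_dimer_monomer)
    if not 1.0 <= r <= 2.0:
        raise ModelViolationError(f"ratio {r} outside the attainable [1, 2] range")
    p = r - 1.0
    if se_r is None:
        return p
    return p, float(se_r)


def dimer_fraction(
    r: float, p: float, se_r: float | None = None, se_p: float | None = None
):
    """Fraction of molecules present as dimers, m_e = (r − 1)/p.

    First-order error propagation from SE(r) and SE(p) when supplied.
    Raises :class:`InfeasibleMixtureError` when (r − 1)/p > 1 (signal too
    bright for a monomer-dimer mixture; use :func:`mixture_solve`).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if r < 1.0:
        raise ModelViolationError("ratio below the pure-monomer value 1")
    m = (r - 1.0) / p
    if m > 1.0 + 1e-12:
        raise InfeasibleMixtureError(
            f"(r-1)/p = {m:.3f} > 1: not attainable by a monomer-dimer mixture")
    m = min(m, 1.0)
    if se_r is None and se_p is None:
        return m
    se_r = se_r or 0.0
    se_p = se_p or 0.0
    se = np.sqrt((se_r / p) ** 2 + ((r - 1.0) * se_p / p ** 2) ** 2)
    return m, float(se)


def mixture_solve(r: float, p: float, orders: tuple[int, int]) -> tuple[float, float]:
    """Number fractions (f₁, f₂) of a two-species oligomer mixture.

    Solves  r = Σ fᵢ·(kᵢ p(1−p) + kᵢ² p²) / Σ fᵢ·kᵢ p  (binomial ⟨q²⟩/⟨q⟩ of
    the number-weighted mixture) for f₂ = 1 − f₁.  The measured ratio must
    lie between the two pure-species ratios 1 + (kᵢ−1)p.
    """
    k1, k2 = orders
    if not (k1 < k2 and k1 >= 1):
        raise ValueError("orders must satisfy 1 <= k1 < k2")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    rho1, rho2 = kmer_brightness_ratio(k1, p), kmer_brightness_ratio(k2, p)
    if not (min(rho1, rho2) - 1e-12 <= r <= max(rho1, rho2) + 1e-12):
        raise InfeasibleMixtureError(
            f"r = {r} outside the attainable range [{rho1:.4f}, {rho2:.4f}] "
            f"for orders {orders} at p = {p}")
    b1 = k1 * p * (1 - p) + k1 ** 2 * p ** 2
    b2 = k2 * p * (1 - p) + k2 ** 2 * p ** 2
    n1, n2 = k1 * p, k2 * p
    # r (n1 f1 + n2 f2) = b1 f1 + b2 f2, f2 = 1 - f1
    denom = (b2 - r * n2) - (b1 - r * n1)
    f1 = (b2 - r * n2) / denom
    f1 = float(np.clip(f1, 0.0, 1.0))
    return f1, 1.0 - f1


def g1_validity_warning(transit_time_s: float, frame_time_s: float, factor: float = 10.0) -> None:
    """Warn when the G1 covariance mode is outside its validity regime
    (transit time not ≫ binned frame time)."""
    if transit_time_s < factor * frame_time_s:
        warnings.warn(
            f"G1 N&B assumes transit time >> frame time; got "
            f"{transit_time_s:.3g} s vs {frame_time_s:.3g} s", stacklevel=2)
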