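"""Camera-FCS diffusion model, per-pixel fitting and PSF calibration.

The observation area of a camera pixel is the convolution of the square
pixel (side a, the binned object-plane pixel size) with the Gaussian PSF
(1/e² radius ω_xy).  The resulting one-component correlation model is

    G(τ) = (1/N) · g(τ)/g(0) + G∞
    g(τ) = ( √(4Dτ + ω²)/(a√π) · (exp(−a²/(4Dτ + ω²)) − 1)
             + erf(a/√(4Dτ + ω²)) )²

with N the number of particles in the effective observation area
A_eff = a²/g(0) and D the diffusion coefficient.  The PSF is calibrated by
requiring the fitted D of a freely diffusing sample to be invariant under
spatial pixel binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf

from .correlator import ACFMap, PixelACF
from .stack import AcquisitionGeometry, ImageStack, ParameterMap

D_WINDOW = (0.01, 10.0)  # µm²/s acceptance window for fitted D
_D_BOUNDS = (1e-3, 1e2)
_N_BOUNDS = (1e-3, 1e6)
_GINF_BOUNDS = (-0.5, 0.5)


@dataclass
class ACFModelParams:
    """Fitted parameters of the (one- or two-component) diffusion model."""

    N: float
    D: float
    Ginf: float = 0.0
    D2: float | None = None
    F2: float = 0.0

    def __post_init__(self) -> None:
        if self.D2 is not None and self.D2 > self.D:
            # slow component is labelled second
            self.D, self.D2 = self.D2, self.D
            self.F2 = 1.0 - self.F2


def model_g(tau, D: float, a_nm: float, w_nm: float) -> np.ndarray:
    """Amplitude factor g(τ) of the camera-FCS model (τ in s, D in µm²/s,
    lengths in nm).  Monotone decreasing in τ with g(0) ∈ (0, 1)."""
    tau = np.asarray(tau, dtype=np.float64)
    s2 = 4.0 * D * 1e6 * tau + w_nm ** 2  # nm²
    s = np.sqrt(s2)
    val = s / (a_nm * np.sqrt(np.pi)) * (np.exp(-(a_nm ** 2) / s2) - 1.0) + erf(a_nm / s)
    return val ** 2


def model_acf(tau, N: float, D: float, Ginf: float, a_nm: float, w_nm: float) -> np.ndarray:
    """One-component model G(τ) = g(τ)/g(0)/N + G∞."""
    return model_g(tau, D, a_nm, w_nm) / model_g(0.0, D, a_nm, w_nm) / N + Ginf


def model_acf_two(tau, N, D, D2, F2, Ginf, a_nm, w_nm) -> np.ndarray:
    """Two-component model: amplitude-weighted sum of two normalized terms
    sharing the geometry."""
    g1 = model_g(tau, D, a_nm, w_nm) / model_g(0.0, D, a_nm, w_nm)
    g2 = model_g(tau, D2, a_nm, w_nm) / model_g(0.0, D2, a_nm, w_nm)
    return ((1.0 - F2) * g1 + F2 * g2) / N + Ginf


def effective_area(geometry: AcquisitionGeometry, binning: int = 1) -> float:
    """Effective observation area A_eff = (binning·a)²/g(0) in µm².

    Always larger than the bare pixel area and monotone increasing in
    binning; tends to the bare area as ω → 0.
    """
    a_nm = geometry.camera_pixel_size_um * 1000.0 / geometry.magnification \
        * geometry.binning * binning
    g0 = model_g(0.0, 1.0, a_nm, geometry.psf_e2_radius_nm)
    return (a_nm / 1000.0) ** 2 / float(g0)


def transit_time(area_um2: float, d_um2_s: float) -> float:
    """Average transit (diffusion) time τ_d = A_eff/(4·D) in seconds."""
    if area_um2 <= 0 or d_um2_s <= 0:
        raise ValueError("area and D must be positive")
    return area_um2 / (4.0 * d_um2_s)


@dataclass
class FitOutcome:
    params: ACFModelParams
    chi2: float
    valid: bool
    reason: str = ""


def _initial_guess(lags, G, Ginf0=0.0):
    amp = G[0] - Ginf0
    N0 = 1.0 / amp if amp > 0 else 10.0
    # half-decay lag -> rough transit time
    target = Ginf0 + 0.5 * amp
    below = np.nonzero(G <= target)[0]
    tau_half = lags[below[0]] if below.size else lags[len(lags) // 2]
    return N0, tau_half


def fit_acf(
    acf: PixelACF,
    geometry: AcquisitionGeometry,
    mode: str = "one_component",
    init: ACFModelParams | None = None,
    weighted: bool = True,
) -> FitOutcome:
    """Weighted trust-region least-squares fit of the diffusion model.

    Validity requires optimizer convergence, positive amplitude and D inside
    the 0.01–10 µm²/s acceptance window.  Three multi-starts are attempted on
    non-convergence.
    """
    lags = np.asarray(acf.lags, dtype=float)
    G = np.asarray(acf.G, dtype=float)
    keep = np.isfinite(G) & (lags > 0)
    lags, G = lags[keep], G[keep]
    sd = np.asarray(acf.sd, dtype=float)[keep]
    if lags.size < 8:
        return FitOutcome(ACFModelParams(np.nan, np.nan), np.nan, False, "too few lags")
    a_nm = geometry.object_pixel_size_nm
    w_nm = geometry.psf_e2_radius_nm
    w = np.ones_like(G)
    if weighted:
        good = np.isfinite(sd) & (sd > 0)
        if good.sum() >= G.size // 2:
            # weight by 1/sd where available; median weight elsewhere
            w = np.where(good, 1.0 / np.where(good, sd, 1.0),
                         np.median(1.0 / sd[good]))

    N0, tau_half = _initial_guess(lags, G)
    a_eff = effective_area(geometry)
    D0 = np.clip(a_eff / (4.0 * tau_half), *_D_BOUNDS)

    if mode == "one_component":
        def resid(p):
            return (model_acf(lags, p[0], p[1], p[2], a_nm, w_nm) - G) * w

        starts = [
            [init.N, init.D, init.Ginf] if init is not None else [N0, D0, 0.0],
            [N0, D0 * 5, 0.0],
            [N0, max(D0 / 5, _D_BOUNDS[0] * 2), 0.0],
        ]
        lb = [_N_BOUNDS[0], _D_BOUNDS[0], _GINF_BOUNDS[0]]
        ub = [_N_BOUNDS[1], _D_BOUNDS[1], _GINF_BOUNDS[1]]
    elif mode == "two_component":
        def resid(p):
            return (model_acf_two(lags, p[0], p[1], p[3], p[4], p[2], a_nm, w_nm) - G) * w

        base = [init.N, init.D, init.Ginf, init.D2 or init.D / 10, init.F2] \
            if init is not None else [N0, D0, 0.0, max(D0 / 20, _D_BOUNDS[0] * 2), 0.3]
        starts = [base,
                  [N0, D0 * 3, 0.0, max(D0 / 50, _D_BOUNDS[0] * 2), 0.5],
                  [N0, D0, 0.0, max(D0 / 5, _D_BOUNDS[0] * 2), 0.1]]
        lb = [_N_BOUNDS[0], _D_BOUNDS[0], _GINF_BOUNDS[0], _D_BOUNDS[0], 0.0]
        ub = [_N_BOUNDS[1], _D_BOUNDS[1], _GINF_BOUNDS[1], _D_BOUNDS[1], 1.0]
    else:
        raise ValueError("mode must be 'one_component' or 'two_component'")

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), method="trf", max_nfev=400)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and best is sol:
            break
    if best is None:
        return FitOutcome(ACFModelParams(np.nan, np.nan), np.nan, False, "non-convergence")

    dof = max(lags.size - len(best.x), 1)
    chi2 = 2.0 * best.cost / dof
    if mode == "one_component":
        params = ACFModelParams(N=best.x[0], D=best.x[1], Ginf=best.x[2])
        Dmain = best.x[1]
    else:
        params = ACFModelParams(N=best.x[0], D=best.x[1], Ginf=best.x[2],
                                D2=best.x[3], F2=best.x[4])
        Dmain = params.D
    amp_ok = (1.0 / params.N) > 0
    d_ok = D_WINDOW[0] < Dmain < D_WINDOW[1]
    valid = bool(best.success and amp_ok and d_ok)
    reason = "" if valid else ("D outside 0.01-10 window" if not d_ok else "non-convergence")
    return FitOutcome(params, float(chi2), valid, reason)


@dataclass
class FitResultMap:
    """Per-pixel fitted parameter maps (all :class:`ParameterMap`)."""

    D: ParameterMap
    N: ParameterMap
    Ginf: ParameterMap
    chi2: ParameterMap
    binning: int = 1

    @property
    def validity(self) -> np.ndarray:
        return self.D.validity


def fit_acf_map(
    acfmap: ACFMap,
    geometry: AcquisitionGeometry,
    mode: str = "one_component",
    two_component_chi2: float | None = None,
    weighted: bool = True,
) -> FitResultMap:
    """Fit every valid pixel of an ACF map.

    When ``two_component_chi2`` is given, pixels whose one-component reduced
    chi² exceeds it are refit with the two-component model.
    """
    import dataclasses as _dc

    H, W = acfmap.shape
    geom = _dc.replace(geometry, binning=acfmap.binning)
    Dm = np.full((H, W), np.nan)
    Nm = np.full((H, W), np.nan)
    Gm = np.full((H, W), np.nan)
    Cm = np.full((H, W), np.nan)
    ok = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            if not acfmap.valid[r, c]:
                continue
            out = fit_acf(acfmap.pixel(r, c), geom, mode=mode, weighted=weighted)
            if (two_component_chi2 is not None and mode == "one_component"
                    and np.isfinite(out.chi2) and out.chi2 > two_component_chi2):
                out2 = fit_acf(acfmap.pixel(r, c), geom, mode="two_component",
                               weighted=weighted)
                if out2.valid and out2.chi2 < out.chi2:
                    out = out2
            Dm[r, c] = out.params.D
            Nm[r, c] = out.params.N
            Gm[r, c] = out.params.Ginf
            Cm[r, c] = out.chi2
            ok[r, c] = out.valid
    kw = dict(binning_used=acfmap.binning)
    finite = ok & np.isfinite(Dm)
    return FitResultMap(
        D=ParameterMap(Dm, finite, "D", "um^2/s", **kw),
        N=ParameterMap(Nm, finite, "N", "particles", **kw),
        Ginf=ParameterMap(Gm, finite, "Ginf", "", **kw),
        chi2=ParameterMap(Cm, finite, "chi2", "", **kw),
        binning=acfmap.binning,
    )


class CalibrationError(RuntimeError):
    """PSF calibration found no interior optimum on the ω grid."""


def calibrate_psf(
    stack: ImageStack,
    geometry: AcquisitionGeometry,
    binnings=(1, 2, 3, 4, 5),
    omega_grid_nm=None,
    bleach_order: int = 8,
    scheme=None,
    lag_range: tuple[float, float] | None = None,
    background: float = 0.0,
) -> tuple[float, pd.DataFrame]:
    """Calibrate ω_xy by pixel-binning invariance of the fitted D.

    For each candidate ω and binning the pixel-averaged ACF of the (freely
    diffusing) calibration stack is fitted; the calibrated ω* minimizes the
    coefficient of variation of D across binnings and must be an interior
    grid point.  Returns (ω*, table of D(ω, binning) with the CV per ω).
    """
    from .correlator import CorrelatorScheme, acf_map

    if scheme is None:
        scheme = CorrelatorScheme()
    binnings = list(binnings)
    if len(binnings) < 3:
        raise ValueError("need at least 3 binnings")
    if omega_grid_nm is None:
        lam = geometry.emission_wavelength_nm
        na = geometry.numerical_aperture
        omega_grid_nm = np.arange(0.6, 1.31, 0.05) * lam / na
    omega_grid_nm = np.asarray(sorted(omega_grid_nm), dtype=float)
    if omega_grid_nm.size < 5:
        raise ValueError("need at least 5 omega candidates")

    # one pixel-averaged ACF per binning; ACFs do not depend on omega
    mean_acfs = []
    for b in binnings:
        amap = acf_map(stack, scheme=scheme, binning=b, bleach_order=bleach_order,
                       lag_range=lag_range, background=background)
        g = np.nanmean(amap.G.reshape(len(amap.lags), -1), axis=1)
        sd = np.nanmean(amap.sd.reshape(len(amap.lags), -1), axis=1) \
            / np.sqrt(max(amap.valid.sum(), 1))
        mean_acfs.append(PixelACF(amap.lags, g, sd, float(amap.mean_intensity.mean())))

    import dataclasses as _dc

    rows = []
    for w_nm in omega_grid_nm:
        for b, acf in zip(binnings, mean_acfs):
            geom = _dc.replace(geometry, psf_e2_radius_nm=float(w_nm), binning=b)
            out = fit_acf(acf, geom)
            rows.append({"omega_nm": float(w_nm), "binning": b,
                         "D": out.params.D, "valid": out.valid})
    table = pd.DataFrame(rows)
    cv = (table.groupby("omega_nm")["D"]
          .agg(lambda d: d.std(ddof=1) / d.mean())
          .rename("cv"))
    table = table.merge(cv.reset_index(), on="omega_nm")
    cvs = cv.to_numpy()
    i = int(np.nanargmin(cvs))
    if i == 0 or i == len(cvs) - 1:
        raise CalibrationError("no interior CV minimum on the omega grid")
    return float(cv.index[i]), table
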