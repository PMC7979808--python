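"""FCS diffusion law: transit time vs observation area across binnings.

For free diffusion the average transit time τ_d = A_eff/(4D) grows linearly
through the origin with the effective observation area.  Sub-resolution
organization bends the plot: trapping in domains gives a positive intercept,
corralling by a meshwork a negative one.  The intercept is estimated by a
straight-line fit of the region-mean transit time over square binnings
(default 1–5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correlator import CorrelatorScheme, acf_map
from .fcs import effective_area, fit_acf_map, transit_time
from .stack import AcquisitionGeometry, ImageStack


class InsufficientDataError(RuntimeError):
    pass


@dataclass
class DiffusionLawResult:
    binnings: list[int]
    areas_um2: np.ndarray
    transit_s: np.ndarray
    transit_sd: np.ndarray
    n_pixels: np.ndarray
    slope: float
    intercept: float
    intercept_se: float
    slope_se: float = np.nan
    classification: str = ""

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "binning": self.binnings,
                "A_eff_um2": self.areas_um2,
                "transit_s": self.transit_s,
                "transit_sd": self.transit_sd,
                "n_pixels": self.n_pixels,
            }
        )


def fit_diffusion_law(
    areas_um2, transit_s, transit_sd=None, weighted: bool = False
) -> tuple[float, float, float, float]:
    """Straight-line fit of τ_d vs A_eff; returns (slope, intercept,
    intercept SE, slope SE).  Unweighted OLS by default; 1/SD² weights by
    flag."""
    areas = np.asarray(areas_um2, dtype=float)
    taus = np.asarray(transit_s, dtype=float)
    if areas.size < 3:
        raise InsufficientDataError("need >= 3 binnings with valid pixels")
    if weighted and transit_sd is not None:
        w = 1.0 / np.square(np.asarray(transit_sd, dtype=float))
        W = np.sum(w)
        xm = np.sum(w * areas) / W
        ym = np.sum(w * taus) / W
        sxx = np.sum(w * (areas - xm) ** 2)
        slope = np.sum(w * (areas - xm) * (taus - ym)) / sxx
        intercept = ym - slope * xm
        resid = taus - (intercept + slope * areas)
        dof = areas.size - 2
        s2 = np.sum(w * resid ** 2) / max(dof, 1)
        slope_se = np.sqrt(s2 / sxx)
        intercept_se = np.sqrt(s2 * (1.0 / W + xm ** 2 / sxx))
        return float(slope), float(intercept), float(intercept_se), float(slope_se)
    res = stats.linregress(areas, taus)
    return (float(res.slope), float(res.intercept),
            float(res.intercept_stderr), float(res.stderr))


def diffusion_law(
    stack: ImageStack,
    geometry: AcquisitionGeometry,
    binnings=(1, 2, 3, 4, 5),
    region_mask: np.ndarray | None = None,
    scheme: CorrelatorScheme = CorrelatorScheme(),
    bleach_order: int = 8,
    lag_range: tuple[float, float] | None = None,
    background: float = 0.0,
    weighted: bool = False,
    z_threshold: float = 2.0,
) -> DiffusionLawResult:
    """Compute the diffusion-law plot and intercept for a stack.

    Per binning, the region-mean transit time A_eff/(4·D_pixel) is averaged
    over valid pixels (inside ``region_mask`` at full resolution, when
    given; a binned pixel is used if every covered full-resolution pixel is
    inside the mask).
    """
    binnings = list(binnings)
    areas, taus, sds, ns, used = [], [], [], [], []
    for b in binnings:
        amap = acf_map(stack, scheme=scheme, binning=b, bleach_order=bleach_order,
                       lag_range=lag_range, background=background)
        fits = fit_acf_map(amap, geometry)
        ok = fits.validity.copy()
        if region_mask is not None:
            H2, W2 = ok.shape
            m = region_mask[: H2 * b, : W2 * b].reshape(H2, b, W2, b).all(axis=(1, 3))
            ok &= m
        if ok.sum() == 0:
            continue
        a_eff = effective_area(geometry, b)
        tt = a_eff / (4.0 * fits.D.values[ok])
        areas.append(a_eff)
        taus.append(float(np.mean(tt)))
        sds.append(float(np.std(tt, ddof=1)) if tt.size > 1 else 0.0)
        ns.append(int(ok.sum()))
        used.append(b)
    if len(used) < 3:
        raise InsufficientDataError("fewer than 3 binnings with valid pixels")
    # weighted fit uses the standard error of each region mean, not the spread
    sems = np.asarray(sds) / np.sqrt(np.maximum(np.asarray(ns), 1))
    slope, intercept, ise, sse = fit_diffusion_law(areas, taus, sems, weighted=weighted)
    result = DiffusionLawResult(
        binnings=used,
        areas_um2=np.asarray(areas),
        transit_s=np.asarray(taus),
        transit_sd=np.asarray(sds),
        n_pixels=np.asarray(ns),
        slope=slope,
        intercept=intercept,
        intercept_se=ise,
        slope_se=sse,
    )
    result.classification = classify_intercept(result, z=z_threshold)
    return result


def classify_intercept(result: DiffusionLawResult, z: float = 2.0) -> str:
    """Diffusion-mode label from the intercept sign at z·SE significance:
    ``free`` when |τ₀| < z·SE, ``confined/domain`` when positive,
    ``meshwork`` when negative."""
    t0, se = result.intercept, result.intercept_se
    if not np.isfinite(se) or abs(t0) < z * se:
        return "free"
    return "confined/domain" if t0 > 0 else "meshwork"
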