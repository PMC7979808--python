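"""Synthetic TIRF image stacks of membrane-diffusing fluorophores.

Generates camera image stacks with known ground truth so that every analysis
stage (correlation, fitting, N&B, super-resolution, artifact correction) can
be validated without real data.  The model:

* each molecule performs free 2-D Brownian motion in a periodic rectangular
  region (fixed molecule count, stationary concentration);
* a molecule is an oligomer of ``k`` subunits; each subunit is fluorescent
  with probability ``p`` (binomial maturation model), so a tandem dimer is on
  average ``1 + p`` times brighter than a monomer;
* each fluorescent subunit deposits a 2-D Gaussian of 1/e² radius ω_xy on the
  pixel grid, integrated analytically over each pixel;
* optional fibre segments capture molecules within one object pixel with
  first-order on/off kinetics; bound molecules diffuse in 1-D along the
  segment (reflecting ends) with their own diffusion coefficient;
* photobleaching switches subunits off permanently at a fixed rate;
* the detector adds Poisson shot noise, an optional EMCCD gain register
  modelled as a per-photoelectron Gamma multiplication (excess noise factor
  ≈ 2 emerges naturally), Gaussian read noise and a constant offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np

from .stack import AcquisitionGeometry, ImageStack


@dataclass(frozen=True)
class Species:
    """One diffusing molecular species.

    ``d_um2_s`` free diffusion coefficient; ``density_per_um2`` molecules per
    µm²; ``oligomer_order`` subunits per molecule; ``p_fluorescent``
    probability a subunit is fluorescent; ``counts_per_fluorophore`` expected
    detected counts per fluorescent subunit per frame (at EM gain 1);
    ``binds_fibres`` whether this species is captured by fibre segments.
    """

    d_um2_s: float
    density_per_um2: float
    oligomer_order: int = 1
    p_fluorescent: float = 1.0
    counts_per_fluorophore: float = 100.0
    binds_fibres: bool = False
    n_molecules: int | None = None
    confine_center_um: tuple[float, float] | None = None
    confine_radius_um: float | None = None
    start_on_fibre: bool = False

    def __post_init__(self) -> None:
        if self.d_um2_s < 0 or self.density_per_um2 < 0:
            raise ValueError("rates, densities and D must be >= 0")
        if (self.confine_center_um is None) != (self.confine_radius_um is None):
            raise ValueError("confinement needs both a centre and a radius")
        if not 0.0 <= self.p_fluorescent <= 1.0:
            raise ValueError("p_fluorescent must be in [0, 1]")
        if self.oligomer_order < 1:
            raise ValueError("oligomer_order must be >= 1")


@dataclass(frozen=True)
class Fibre:
    """A line segment (µm endpoints) with two-state binding kinetics."""

    x0: float
    y0: float
    x1: float
    y1: float
    k_on: float = 10.0
    k_off: float = 0.1
    bound_d_um2_s: float = 0.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.bound_d_um2_s < 0:
            raise ValueError("rates and D must be >= 0")


@dataclass(frozen=True)
class Detector:
    """EMCCD-like detector: counts = Gamma(Poisson photoelectrons, gain)
    + N(0, σ₀²) + offset."""

    offset: float = 100.0
    read_noise_sd: float = 2.0
    em_gain: float = 1.0
    use_em_gamma: bool = False


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic acquisition.

    Defaults follow the EMCCD configuration used throughout: 2 ms frames and
    240 nm object-plane pixels.  The imaged region is ``shape`` pixels; the
    simulation box coincides with the imaged region and uses periodic
    boundaries, so concentration is stationary.
    """

    seed: int = 0
    shape: tuple[int, int] = (32, 32)
    n_frames: int = 2000
    frame_time: float = 0.002
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    species: list[Species] = field(default_factory=list)
    fibres: list[Fibre] = field(default_factory=list)
    detector: Detector = field(default_factory=Detector)
    bleach_rate: float = 0.0
    capture_distance_px: float = 1.0
    burn_in_frames: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or min(self.shape) < 1:
            raise ValueError("n_frames and shape must be positive")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")

    @property
    def region_um(self) -> tuple[float, float]:
        a = self.geometry.object_pixel_size_nm / 1000.0
        return (self.shape[0] * a, self.shape[1] * a)


@dataclass
class GroundTruth:
    """Per-molecule trajectories and activation outcomes on the frame grid."""

    positions_um: np.ndarray  # (T, M, 2) as (x, y)
    species_index: np.ndarray  # (M,)
    n_fluorescent: np.ndarray  # (M,) fluorescent subunits at t=0
    bound_state: np.ndarray | None  # (T, M) bool, None when no fibres
    fibre_mask: np.ndarray | None  # (H, W) bool at pixel resolution

    def trajectory_frame(self) -> "object":
        import pandas as pd

        T, M, _ = self.positions_um.shape
        t = np.repeat(np.arange(T), M)
        m = np.tile(np.arange(M), T)
        out = {
            "frame": t,
            "molecule": m,
            "x_um": self.positions_um[:, :, 0].ravel(),
            "y_um": self.positions_um[:, :, 1].ravel(),
        }
        if self.bound_state is not None:
            out["bound"] = self.bound_state.ravel()
        return pd.DataFrame(out)


@numba.njit(cache=True)
def _deposit(expected, xs, ys, amps, sigma_px, halfw):  # pragma: no cover - jit
    """Add pixel-integrated Gaussians to ``expected`` (T, H, W), periodic.

    xs/ys in pixel units (column/row), amps (T, M) expected counts per
    molecule per frame.
    """
    T, H, W = expected.shape
    M = xs.shape[1]
    inv = 1.0 / (sigma_px * math.sqrt(2.0))
    n = 2 * halfw + 1
    fx = np.empty(n)
    fy = np.empty(n)
    for t in range(T):
        for m in range(M):
            a = amps[t, m]
            if a <= 0.0:
                continue
            x = xs[t, m]
            y = ys[t, m]
            j0 = int(math.floor(x)) - halfw
            i0 = int(math.floor(y)) - halfw
            e_prev = math.erf((j0 - x) * inv)
            for dj in range(n):
                e_next = math.erf((j0 + dj + 1 - x) * inv)
                fx[dj] = 0.5 * (e_next - e_prev)
                e_prev = e_next
            e_prev = math.erf((i0 - y) * inv)
            for di in range(n):
                e_next = math.erf((i0 + di + 1 - y) * inv)
                fy[di] = 0.5 * (e_next - e_prev)
                e_prev = e_next
            for di in range(n):
                ii = (i0 + di) % H
                afy = a * fy[di]
                for dj in range(n):
                    expected[t, ii, (j0 + dj) % W] += afy * fx[dj]


def _point_segment(px, py, f):
    """Closest point and distance from (px, py) to segment f (vectorized)."""
    vx, vy = f.x1 - f.x0, f.y1 - f.y0
    L2 = vx * vx + vy * vy
    if L2 == 0:
        s = np.zeros_like(px)
    else:
        s = np.clip(((px - f.x0) * vx + (py - f.y0) * vy) / L2, 0.0, 1.0)
    cx, cy = f.x0 + s * vx, f.y0 + s * vy
    d = np.hypot(px - cx, py - cy)
    return d, s


def simulate_stack(cfg: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate one acquisition; returns the camera stack and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.shape
    a_um = cfg.geometry.object_pixel_size_nm / 1000.0
    Ly, Lx = H * a_um, W * a_um
    T = cfg.n_frames + cfg.burn_in_frames
    dt = cfg.frame_time
    sigma_px = cfg.geometry.psf_e2_radius_nm / 2.0 / cfg.geometry.object_pixel_size_nm
    halfw = max(2, int(math.ceil(4.0 * sigma_px)))

    counts = [
        s.n_molecules if s.n_molecules is not None
        else max(0, int(round(s.density_per_um2 * Lx * Ly)))
        for s in cfg.species
    ]
    M = int(sum(counts))
    species_index = np.repeat(np.arange(len(cfg.species)), counts).astype(np.int64)

    positions = np.zeros((T, max(M, 1), 2), dtype=np.float64)
    bound = None
    if M > 0:
        x = rng.uniform(0, Lx, M)
        y = rng.uniform(0, Ly, M)
        conf = np.array([cfg.species[i].confine_center_um is not None
                         for i in species_index])
        for m in np.flatnonzero(conf):
            sp = cfg.species[species_index[m]]
            cx0, cy0 = sp.confine_center_um
            rad = sp.confine_radius_um
            rr = rad * math.sqrt(rng.random())
            th = rng.uniform(0, 2 * math.pi)
            x[m] = cx0 + rr * math.cos(th)
            y[m] = cy0 + rr * math.sin(th)
        D = np.array([cfg.species[i].d_um2_s for i in species_index])
        binds = np.array([cfg.species[i].binds_fibres for i in species_index])
        starts_bound = np.array([cfg.species[i].start_on_fibre for i in species_index])
        if starts_bound.any() and not cfg.fibres:
            raise ValueError("start_on_fibre requires at least one fibre")
        use_fibres = bool(cfg.fibres) and (binds.any() or starts_bound.any())
        if not use_fibres and not conf.any():
            steps = rng.normal(0.0, 1.0, (T - 1, M, 2)) * np.sqrt(2 * D * dt)[None, :, None]
            positions[0, :, 0], positions[0, :, 1] = x, y
            positions[1:, :, 0] = x[None, :] + np.cumsum(steps[:, :, 0], axis=0)
            positions[1:, :, 1] = y[None, :] + np.cumsum(steps[:, :, 1], axis=0)
            positions[:, :, 0] %= Lx
            positions[:, :, 1] %= Ly
        else:
            bound = np.zeros((T, M), dtype=bool)
            fib_idx = np.full(M, -1, dtype=np.int64)
            cap_um = cfg.capture_distance_px * a_um
            is_bound = np.zeros(M, dtype=bool)
            for m in np.flatnonzero(starts_bound):
                fi = int(rng.integers(len(cfg.fibres)))
                f = cfg.fibres[fi]
                s = rng.random()
                x[m] = f.x0 + s * (f.x1 - f.x0)
                y[m] = f.y0 + s * (f.y1 - f.y0)
                is_bound[m] = True
                fib_idx[m] = fi
            bound[0] = is_bound
            positions[0, :, 0], positions[0, :, 1] = x, y
            for t in range(1, T):
                free = ~is_bound
                # free motion
                step = rng.normal(0.0, 1.0, (M, 2)) * np.sqrt(2 * D * dt)[:, None]
                x = np.where(free, (x + step[:, 0]) % Lx, x)
                y = np.where(free, (y + step[:, 1]) % Ly, y)
                # radial clamp into the confinement disc
                if conf.any():
                    for si, sp in enumerate(cfg.species):
                        if sp.confine_center_um is None:
                            continue
                        sel = species_index == si
                        cx0, cy0 = sp.confine_center_um
                        dx, dy = x[sel] - cx0, y[sel] - cy0
                        rr = np.hypot(dx, dy)
                        out = rr > sp.confine_radius_um
                        if out.any():
                            scale = np.where(out, sp.confine_radius_um / np.maximum(rr, 1e-12), 1.0)
                            x[sel] = cx0 + dx * scale
                            y[sel] = cy0 + dy * scale
                # bound: 1-D diffusion along the fibre, reflecting ends
                for fi, f in enumerate(cfg.fibres):
                    onf = is_bound & (fib_idx == fi)
                    if onf.any():
                        vx, vy = f.x1 - f.x0, f.y1 - f.y0
                        L = math.hypot(vx, vy)
                        _, s = _point_segment(x[onf], y[onf], f)
                        Db = f.bound_d_um2_s
                        ds = rng.normal(0.0, 1.0, onf.sum()) * math.sqrt(2 * Db * dt) / max(L, 1e-12)
                        s2 = s + ds
                        # reflect into [0, 1]
                        s2 = np.abs(s2)
                        s2 = 1.0 - np.abs(1.0 - (s2 % 2.0))
                        x[onf] = f.x0 + s2 * vx
                        y[onf] = f.y0 + s2 * vy
                        # unbinding
                        p_off = 1.0 - math.exp(-f.k_off * dt)
                        rel = rng.random(onf.sum()) < p_off
                        idx = np.flatnonzero(onf)[rel]
                        is_bound[idx] = False
                        fib_idx[idx] = -1
                # binding: capture free binding-competent molecules near fibres
                cand = (~is_bound) & binds
                if cand.any():
                    for fi, f in enumerate(cfg.fibres):
                        c = np.flatnonzero(cand & ~is_bound)
                        if c.size == 0:
                            break
                        d, _ = _point_segment(x[c], y[c], f)
                        p_on = 1.0 - math.exp(-f.k_on * dt)
                        hit = (d <= cap_um) & (rng.random(c.size) < p_on)
                        is_bound[c[hit]] = True
                        fib_idx[c[hit]] = fi
                positions[t, :, 0], positions[t, :, 1] = x, y
                bound[t] = is_bound

    if cfg.burn_in_frames:
        positions = positions[cfg.burn_in_frames:]
        if bound is not None:
            bound = bound[cfg.burn_in_frames:]
        T = cfg.n_frames

    # fluorophore activation and bleaching
    n_fluo = np.zeros(max(M, 1), dtype=np.int64)
    amps = np.zeros((T, max(M, 1)), dtype=np.float64)
    if M > 0:
        for m in range(M):
            sp = cfg.species[species_index[m]]
            q = rng.binomial(sp.oligomer_order, sp.p_fluorescent)
            n_fluo[m] = q
            if q == 0:
                continue
            eps = sp.counts_per_fluorophore
            if cfg.bleach_rate > 0:
                # each subunit bleaches at an exponential time
                t_bleach = rng.exponential(1.0 / cfg.bleach_rate, q) / dt
                alive = (np.arange(T)[:, None] < t_bleach[None, :]).sum(axis=1)
                amps[:, m] = eps * alive
            else:
                amps[:, m] = eps * q

    expected = np.zeros((T, H, W), dtype=np.float64)
    if M > 0 and amps.max() > 0:
        xs = positions[:, :, 0] / a_um  # column coordinate
        ys = positions[:, :, 1] / a_um  # row coordinate
        _deposit(expected, xs, ys, amps, sigma_px, halfw)

    det = cfg.detector
    photons = rng.poisson(expected)
    if det.use_em_gamma and det.em_gain != 1.0:
        signal = np.zeros_like(expected)
        nz = photons > 0
        signal[nz] = rng.gamma(photons[nz].astype(np.float64), det.em_gain)
    else:
        signal = photons * det.em_gain
    out = signal + rng.normal(0.0, det.read_noise_sd, signal.shape) + det.offset
    out = np.clip(np.rint(out), 0, 65535).astype(np.uint16)

    fibre_mask = None
    if cfg.fibres:
        rows, cols = np.indices((H, W))
        px = (cols + 0.5) * a_um
        py = (rows + 0.5) * a_um
        fibre_mask = np.zeros((H, W), dtype=bool)
        for f in cfg.fibres:
            d, _ = _point_segment(px, py, f)
            fibre_mask |= d <= cfg.capture_distance_px * a_um

    stack = ImageStack(out, frame_time=dt, geometry=cfg.geometry, bit_depth=16)
    truth = GroundTruth(
        positions_um=positions if M > 0 else positions[:, :0],
        species_index=species_index,
        n_fluorescent=n_fluo[:M],
        bound_state=bound,
        fibre_mask=fibre_mask,
    )
    return stack, truth


def simulate_bleach_trace(
    rate: float,
    n_frames: int,
    frame_time: float,
    amplitude: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expected (or Poisson-sampled, when ``rng`` given) exponential bleach
    trace ``amplitude · exp(−rate·t)`` on the frame grid."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.arange(n_frames) * frame_time
    expected = amplitude * np.exp(-rate * t)
    if rng is None:
        return expected
    return rng.poisson(expected).astype(np.float64)
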