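"""Shared synthetic-microscopy fixtures.

The heavy simulated stacks are session-scoped and reused across module tests
and the acceptance suite.  Every fixture is fully seeded; the configurations
are the study conditions (frame times, pixel sizes, densities, brightnesses)
the analyses are designed for, scaled down in duration and field of view so
the suite runs on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

import imflux as ix
from imflux.simulate import _point_segment

LAG_RANGE = (0.002, 0.5)  # fitting window, seconds
OFFSET = 100.0


@pytest.fixture(scope="session")
def geometry():
    """EMCCD at 100x: 240 nm pixels, calibrated 364 nm PSF at 565 nm."""
    return ix.AcquisitionGeometry()


@pytest.fixture(scope="session")
def free_stack(geometry):
    """Freely diffusing single species, D = 2 µm²/s, 20,000 x 2 ms frames."""
    cfg = ix.SimulationConfig(
        seed=5, shape=(32, 32), n_frames=20000, frame_time=0.002,
        geometry=geometry,
        species=[ix.Species(d_um2_s=2.0, density_per_um2=15.0,
                            counts_per_fluorophore=120.0)],
        detector=ix.Detector(offset=OFFSET, read_noise_sd=2.0),
    )
    stack, truth = ix.simulate_stack(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def free_fits(free_stack, geometry):
    stack, _, _ = free_stack
    amap = ix.acf_map(stack, binning=1, bleach_order=8,
                      lag_range=LAG_RANGE, background=OFFSET)
    fits = ix.fit_acf_map(amap, geometry)
    return amap, fits


@pytest.fixture(scope="session")
def free_dlaw(free_stack, geometry):
    stack, _, _ = free_stack
    return ix.diffusion_law(stack, geometry, lag_range=LAG_RANGE,
                            background=OFFSET)


@pytest.fixture(scope="session")
def nb_ratio_stacks(geometry):
    """Monomer and tandem-dimer pools at p_fluorescent = 0.55, identical
    per-fluorophore brightness; used for the brightness-ratio check."""
    out = {}
    for name, k, seed in (("monomer", 1, 2041), ("dimer", 2, 1041)):
        cfg = ix.SimulationConfig(
            seed=seed, shape=(24, 24), n_frames=40000, frame_time=0.002,
            geometry=geometry,
            species=[ix.Species(d_um2_s=0.5, density_per_um2=10.0,
                                oligomer_order=k, p_fluorescent=0.55,
                                counts_per_fluorophore=150.0)],
            detector=ix.Detector(offset=OFFSET, read_noise_sd=2.0),
        )
        stack, _ = ix.simulate_stack(cfg)
        out[name] = stack
    return out


@pytest.fixture(scope="session")
def nb_brightness(nb_ratio_stacks):
    """Mean G1 brightness of the monomer and dimer stacks after the
    standard 10-frame sum binning to 20 ms exposure."""
    dark = ix.DarkCalibration(offset=OFFSET * 10, read_variance=10 * 4.0)
    means = {}
    for name, stack in nb_ratio_stacks.items():
        binned = ix.bin_temporal(stack, 10, mode="sum")
        res = ix.nb_maps(binned, dark, mode="G1", bleach_order=8,
                         intensity_filter=None)
        means[name] = res
    return means


PIPELINE_FIBRES = [
    ix.Fibre(1.0, 1.0, 7.0, 7.0, k_on=0.0, k_off=0.0, bound_d_um2_s=3.0),
    ix.Fibre(1.5, 8.0, 7.0, 3.0, k_on=0.0, k_off=0.0, bound_d_um2_s=3.0),
]


@pytest.fixture(scope="session")
def fibre_blob_stack(geometry):
    """Two fibres carrying fast 1-D diffusers plus a slow bright confined
    cluster (the moving artifact) and a dilute free background pool."""
    cfg = ix.SimulationConfig(
        seed=11, shape=(48, 48), n_frames=20000, frame_time=0.004,
        geometry=geometry,
        species=[
            ix.Species(d_um2_s=2.0, density_per_um2=0.0, n_molecules=70,
                       counts_per_fluorophore=300.0, binds_fibres=True,
                       start_on_fibre=True),
            ix.Species(d_um2_s=2.0, density_per_um2=0.3,
                       counts_per_fluorophore=300.0),
            ix.Species(d_um2_s=0.05, density_per_um2=0.0, n_molecules=30,
                       oligomer_order=4, counts_per_fluorophore=300.0,
                       confine_center_um=(9.5, 9.0), confine_radius_um=1.0),
        ],
        fibres=PIPELINE_FIBRES,
        detector=ix.Detector(offset=OFFSET, read_noise_sd=2.0),
    )
    stack, truth = ix.simulate_stack(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def fibre_core_mask(fibre_blob_stack):
    """Pixels within half a pixel of a fibre centre line (the true
    structure, tighter than the binding capture band)."""
    stack, _, cfg = fibre_blob_stack
    a_um = cfg.geometry.object_pixel_size_nm / 1000.0
    rows, cols = np.indices(cfg.shape)
    px, py = (cols + 0.5) * a_um, (rows + 0.5) * a_um
    core = np.zeros(cfg.shape, dtype=bool)
    for f in PIPELINE_FIBRES:
        d, _ = _point_segment(px, py, f)
        core |= d <= 0.5 * a_um
    return core


@pytest.fixture(scope="session")
def fibre_maps(fibre_blob_stack, geometry):
    """D map and SRRF image of the fibre/blob stack."""
    stack, _, _ = fibre_blob_stack
    amap = ix.acf_map(stack, binning=1, bleach_order=8, background=OFFSET)
    fits = ix.fit_acf_map(amap, geometry)
    sr = ix.srrf(stack, ix.SRRFParams())
    return fits, sr


@pytest.fixture(scope="session")
def pipeline_result(fibre_blob_stack, fibre_maps):
    import warnings

    stack, _, _ = fibre_blob_stack
    fits, sr = fibre_maps
    mask = ix.tirf_mask(stack.mean_image(), 150.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr, info = ix.d_histogram_threshold(fits.D, mask)
    res = ix.correct_superres(sr, mask, fits.D, thr)
    return res, thr, info, mask


@pytest.fixture(scope="session")
def trapping_dlaw(geometry):
    """Partially trapped pool: transient binding to parallel fibres adds a
    dwell time, bending the diffusion law toward a positive intercept."""
    fibres = [ix.Fibre(0.0, y, 7.7, y, k_on=15.0, k_off=5.0,
                       bound_d_um2_s=0.05)
              for y in (0.9, 1.9, 2.9, 3.9, 4.9, 5.9, 6.9)]
    cfg = ix.SimulationConfig(
        seed=9, shape=(32, 32), n_frames=30000, frame_time=0.002,
        geometry=geometry,
        species=[ix.Species(d_um2_s=2.0, density_per_um2=12.0,
                            counts_per_fluorophore=120.0, binds_fibres=True)],
        fibres=fibres,
        detector=ix.Detector(offset=OFFSET, read_noise_sd=2.0),
        burn_in_frames=2000,
    )
    stack, _ = ix.simulate_stack(cfg)
    return ix.diffusion_law(stack, geometry, lag_range=LAG_RANGE,
                            background=OFFSET, weighted=True)
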