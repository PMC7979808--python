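"""Structured run configuration (YAML) shared by the CLI stages.

One file holds geometry, correlator, fitting, N&B, SRRF and pipeline
parameters plus the RNG seed; every CLI run logs the fully resolved
configuration next to its outputs so runs are reproducible from the
manifest alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
import platform
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "geometry": {
        "camera_pixel_size_um": 24.0,
        "magnification": 100.0,
        "psf_e2_radius_nm": 364.0,
        "emission_wavelength_nm": 565.0,
        "numerical_aperture": 1.49,
        "binning": 1,
    },
    "correlator": {"p": 16, "q": 12, "bleach_order": 8, "lag_min_s": None, "lag_max_s": None},
    "fit": {"mode": "one_component", "two_component_chi2": 2.0, "weighted": True},
    "diffusion_law": {"binnings": [1, 2, 3, 4, 5], "z_threshold": 2.0},
    "nandb": {"temporal_bin": 10, "mode": "G1", "intensity_filter": "otsu"},
    "srrf": {
        "ring_radius": 0.5,
        "magnification": 5,
        "axes_in_ring": 6,
        "temporal_mode": "TRAC2",
        "temporal_bin": 100,
    },
    "sofi": {"order": 2},
    "pipeline": {"tirf_threshold": "otsu", "d_fallback": 0.2, "hist_bins": 40},
    "simulation": {
        "shape": [32, 32],
        "n_frames": 2000,
        "frame_time": 0.002,
        "species": [
            {
                "d_um2_s": 2.0,
                "density_per_um2": 1.0,
                "oligomer_order": 1,
                "p_fluorescent": 1.0,
                "counts_per_fluorophore": 100.0,
                "binds_fibres": False,
            }
        ],
        "fibres": [],
        "detector": {"offset": 100.0, "read_noise_sd": 2.0, "em_gain": 1.0, "use_em_gamma": False},
        "bleach_rate": 0.0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve a configuration: defaults <- file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    cfg: dict,
    inputs: dict[str, str] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    """Write the run manifest (exactly one per output directory)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": cfg,
        "seed": cfg.get("seed"),
        "input_hashes": inputs or {},
        "outputs": outputs or [],
        "tool_version": __version__,
        "python": platform.python_version(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
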