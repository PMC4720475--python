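"""Structured configuration: documented defaults plus YAML overrides.

The configuration mirrors the module surfaces: ``sonar`` keys match
``SonarParams`` fields, ``units`` carries the per-unit geographic and
calibration data, ``detector``/``tdoa``/``boat``/``alert`` hold the
algorithm parameters.  ``load_config`` deep-merges a user YAML file over
the defaults, so a file only needs the keys it changes.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .geometry import UnitConfig

DEFAULTS: dict = {
    "sonar": {
        "source_level": 160.0,
        "f_min": 5000.0,
        "f_max": 15000.0,
        "spreading_k": 20.0,
        "absorption_db_km": 0.72,
        "detection_threshold_db": 5.0,
        "f_sampl": 100000.0,
        "detection_index": 9.0,
    },
    "noise": {
        # Wenz spectral levels [dB re 1 uPa/sqrt(Hz)] at the band centroid
        "table": {0: {8660.0: 29.0}, 4: {8660.0: 48.0}},
        "wideband_offset": 0.0,
        # site-measured detection ranges after the wide-band offset, [m]
        "real_range_best": 3700.0,
        "real_range_worst": 1500.0,
    },
    "array": {"spacing": 5.0, "depth_offset": 5.0, "sound_speed": 1500.0},
    "units": [
        {"name": "unit_west", "lat": 44.2965, "lon": 9.1980, "depth": 20.0,
         "lc": 3.43e-3, "psi0": 30.0, "declination": 0.0},
        {"name": "unit_east", "lat": 44.2965, "lon": 9.2205, "depth": 20.0,
         "lc": 3.46e-3, "psi0": -80.0, "declination": 0.0},
    ],
    "detector": {
        "band": [5000.0, 15000.0],
        "l_threshold_bins": 2.0,
        "window_p": 10,
        "w_low": 0.8,
        "w_threshold": 0.64,
        "min_event_columns": 3,
        "slope_window": 40,
        "equalize": False,
        "gate_enabled": True,
    },
    "tdoa": {"band": [3000.0, 23000.0], "residual_tol_samples": 2.0},
    "boat": {"window_s": 0.008, "n_sigma": 4.0},
    "alert": {"hold_time_s": 600.0, "sector_side_m": 2000.0, "n_sectors": 5},
    "io": {"full_scale_db": 135.0, "fs": 100000.0},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(str(Path(path))) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULTS, user)


def unit_configs(config: dict) -> list[UnitConfig]:
    return [UnitConfig(**u) for u in config["units"]]
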