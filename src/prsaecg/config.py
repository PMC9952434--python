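"""Default analysis configuration and YAML loading.

Every numeric constant used by an analysis stage is reachable from this
single mapping, so a run is fully described by one config file.  Values
are the pipeline defaults: 2–26 Hz zero-phase band-pass, 20 % ectopic
rule, DC half-window L=12, PRD half-window L=20 with anchor span M=9,
11-sample median window, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, and the
90/360/two-thirds T-window rule.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config"]

_DEFAULTS: dict = {
    "signal": {
        "fs": 250.0,
        "gain": 1.0,
        "columns": {"v_r": "v_r", "v_l": "v_l", "v_f": "v_f", "v_b": "v_b"},
    },
    "filter": {"low_cut_hz": 2.0, "high_cut_hz": 26.0, "order": 4},
    "vcg": {"coeff_file": None},  # None -> packaged coefficient file
    "delineation": {
        "ectopic_threshold": 0.20,
        "refractory_s": 0.25,
        "rr_mode": "preceding",
        "qrs_mark": "r_peak",
        "twave": {"ton_offset_ms": 90.0, "tend_cap_ms": 360.0,
                  "tend_rr_fraction": 2.0 / 3.0, "rr_threshold_ms": 720.0},
    },
    "hrv": {
        "lf_band_hz": [0.04, 0.15],
        "hf_band_hz": [0.15, 0.4],
        "resample_fs_hz": 4.0,
    },
    "dc": {"half_window": 12, "exclude_large_prolongations": False},
    "prd": {"half_window": 20, "anchor_span": 9, "median_window": 11,
            "norm_floor_uv": 5.0},
    "simulate": {
        "n_subjects": 17,
        "master_seed": 0,
        "rest": {"twave_osc_amp_deg": 6.0},
        "stress": {"twave_osc_amp_deg": 12.0},
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, recursively updated by an optional YAML file."""
    cfg = default_config()
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if k not in dst:
                raise KeyError(f"unknown config key: {k!r}")
            if isinstance(v, dict) and isinstance(dst[k], dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(cfg, user)
    return cfg
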