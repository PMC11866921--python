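"""Workflow configuration: one nested document holding every threshold.

Defaults mirror the tolerances used throughout the study design this
package automates: ±5 mDa accurate-mass windows, ±0.1 min retention
time, a 5x blank-subtraction factor, tolerant regression constraints,
and the candidate-ranking defaults (top 25, 5th-percentile thresholds).
A YAML file with the same nesting overrides any subset; unknown keys are
rejected by name so typos cannot silently disable a filter.
"""

from __future__ import annotations

import copy
import io
import json
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict[str, Any] = {
    # global ion chemistry
    "adduct": "[M+H]+",
    "mz_tol_mda": 5.0,          # accurate-mass window, absolute mDa
    "rt_tol_min": 0.1,          # retention-time window, minutes
    "prioritize": {
        "blank_factor": 5.0,            # 2 h max must exceed k x 0 h mean
        "alpha": 0.05,                  # one-sided slope test
        "r2_relaxed": 0.7,              # tolerant branch for saturated TPs
        "min_conc_levels": 2,           # detected in >= this many conc arms
        "min_replicate_detections": 2,  # within at least one 2 h mixture arm
        "min_intensity": 0.0,           # detection floor for "present"
        "replicate_mode": "mean",       # "mean" | "per_replicate"
    },
    "suspects": {
        # metabolic-logic formula deltas applied to each parent
        "logic_deltas": ["+O", "+O2", "-H2+O", "+H2O", "-H2", "+H2",
                         "+H2O2", "-CH2", "-C2HF3"],
    },
    "linking": {
        "single_parent_ratio": 5.0,   # mixture / other-parent single run
        "detection_floor": 0.0,
    },
    "annotation": {
        "background_factor": 2.0,     # flanking-spectrum removal factor
        "rel_intensity_floor": 0.01,  # of base peak, applied after removal
        "fragment_tol_mda": 5.0,
        "isolation_window_mz": 0.5,   # precursor <-> feature mapping
        "fragment_depth": 2,          # bond-break recursion depth
        "hydrogen_tolerance": 1,      # +-H on fragment formulas
        "bounds": {"C": 20, "H": 40, "N": 5, "O": 8, "S": 2, "F": 6},
    },
    "ranking": {
        "forbidden_elements": ["Cl", "Br", "Si", "P"],
        "logp_tolerance": 2.0,        # elution-order filter slack
        "top_n": 25,
        "threshold_percentile": 5.0,  # suspect-derived metric thresholds
        "percentile_method": "lower", # attained value; "linear" interpolates
        "min_calibration_suspects": 5,
        "fit_direction": "max",       # MCS fit: max | candidate | parent
        "mcs_timeout_s": 2.0,
        "ann_operand": "measured",    # annotation score vs measured spectrum
    },
    "identification": {
        "msigma_max": 100.0,          # isotope-fit acceptance
        "annotation_floor": 0.2,      # min annotation support for level 3
    },
    "quantitation": {
        "min_points": 5,
        "min_r2": 0.99,
        "max_residual_fraction": 0.30,
        "weighting": "none",          # "none" | "1/x"
        "rf_uncertainty_factor": 5.0, # predicted-RF band
        "shared_tp_mode": "both",     # "both" | "split" for multi-parent TPs
    },
    "report": {
        "plots": True,
    },
}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown config key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config key {here!r} must be a mapping")
            _merge(base[key], value, here)
        else:
            base[key] = value
    return base


def load_config(path: str | None = None) -> dict[str, Any]:
    """Defaults, optionally overridden by a YAML document."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError("config file must contain a mapping")
    return _merge(cfg, doc)


def dump_config(cfg: Mapping[str, Any]) -> str:
    """Canonical YAML rendering (used to echo defaults into the run log)."""
    return yaml.safe_dump(dict(cfg), sort_keys=True)
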