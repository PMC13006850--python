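"""Default configuration and YAML loading/validation.

Every threshold used by the pipeline lives here so that a single YAML file
documents a run: filtering band and order, the 200 μV epoch-rejection rule,
channel-quality and minimum-night feasibility rules, slow-oscillation and
spindle criteria, behavioral outlier bounds, and the synthetic-data targets.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

#: candidate frontal-occipital derivations of the headband montage
CANDIDATE_CHANNELS = ["F7-O1", "F8-O2", "Fpz-O1", "Fpz-O2"]

DEFAULTS: dict[str, Any] = {
    "preprocess": {
        "filter": {"lo": 0.3, "hi": 40.0, "order": 300},
        "reject_uV": 200.0,  # max |demeaned sample| per 30-s epoch
        "quality_threshold": 0.5,
        "candidate_channels": list(CANDIDATE_CHANNELS),
    },
    "so": {
        "bp_lo": 0.3,
        "bp_hi": 4.0,
        "neg_amp_uV": 33.0,
        "p2p_amp_uV": 61.0,
        "neg_dur_min_ms": 125.0,
        "neg_dur_max_ms": 1500.0,
        "pos_dur_max_ms": 1000.0,
    },
    "spindle": {
        "sigma_lo": 11.0,
        "sigma_hi": 16.0,
        "broad_lo": 0.4,
        "broad_hi": 30.0,
        "win_s": 0.3,
        "step_s": 0.1,
        "thr_relpow": 1.6,  # z of log10 relative sigma power
        "thr_corr": 0.69,
        "thr_cov": 1.3,  # z-score of log covariance against the 30-s baseline
        "dur_min_s": 0.5,
        "dur_max_s": 2.5,
    },
    "metrics": {
        "min_nights": 4,
        "density_denominator": "scored",  # or "artifact_free"
    },
    "scoring": {
        "gonogo_rt_bounds_ms": [200.0, 900.0],
        "simon_rt_bounds_ms": [300.0, 3000.0],
        "commission_denominator": "all_nogo",  # or "correct_go"
        "simon_correct_only": True,
    },
    "stats": {
        "latent_scale": 1.0,
        "so_density_outlier_z": 3.0,
        "n_boot": 1000,
    },
    "simulate": {
        "n_participants": 3,
        "n_nights": 4,
        "fs": 250.0,
        "n_epochs": 931,  # ≈ 465 min in bed, the cohort-mean time-in-bed scale
        # cohort-mean stage minutes the hypnogram chain is calibrated to
        "stage_target_min": {"W": 48.11, "N1": 34.60, "N2": 212.04, "N3": 64.22, "REM": 106.50},
        # mean stage dwell time in 30-s epochs (bout length of each stage)
        "stage_dwell_epochs": {"W": 2.0, "N1": 1.5, "N2": 10.0, "N3": 8.0, "REM": 12.0},
        "so_density_per_min": 4.2,
        "spindle_density_per_min": 1.52,
        "so_amp_uV": 120.0,  # raw p2p; measures ~86 μV after the 0.3-40 Hz chain
        "spindle_amp_uV": 20.0,  # peak amplitude of the Hann-windowed burst
        "spindle_freq_hz": 13.0,
        "noise_rms_uV": 15.0,
        "noise_exponent": 1.0,  # 1/f^a power slope of the background
        "behavior": {
            "beta0": 430.0,
            "betas": {"so_density": 0.0, "spindle_density": 0.0, "waso_min": 0.0},
            "var_between": 2404.27,
            "var_within": 1440.80,
            "family": "gaussian",
            "zero_inflation_prob": 0.0,
        },
    },
    "model": {
        "outcome": "outcome",
        "predictors": ["so_density", "spindle_density", "waso_min"],
        "family": "gaussian",
        "zero_inflated": False,
    },
}


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


def default_config() -> dict[str, Any]:
    """A deep copy of the built-in defaults."""
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def _validate(cfg: dict[str, Any]) -> None:
    pp = cfg["preprocess"]
    if not 0.0 <= pp["quality_threshold"] <= 1.0:
        raise ConfigError("preprocess.quality_threshold must lie in [0, 1]")
    f = pp["filter"]
    if not 0 < f["lo"] < f["hi"]:
        raise ConfigError("preprocess.filter requires 0 < lo < hi")
    if pp["reject_uV"] <= 0:
        raise ConfigError("preprocess.reject_uV must be positive")
    sp = cfg["spindle"]
    if not sp["dur_min_s"] < sp["dur_max_s"]:
        raise ConfigError("spindle.dur_min_s must be below dur_max_s")
    if not sp["win_s"] > sp["step_s"] > 0:
        raise ConfigError("spindle window must exceed step, both positive")
    so = cfg["so"]
    if not so["neg_dur_min_ms"] < so["neg_dur_max_ms"]:
        raise ConfigError("so negative-duration bounds out of order")
    if cfg["metrics"]["min_nights"] < 1:
        raise ConfigError("metrics.min_nights must be at least 1")
    sim = cfg["simulate"]
    if sim["so_density_per_min"] < 0 or sim["spindle_density_per_min"] < 0:
        raise ConfigError("simulated event densities must be non-negative")


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config merged over the defaults and validate it.

    Unknown keys are rejected so typos fail loudly rather than silently
    falling back to a default.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = _merge(cfg, user)
    _validate(cfg)
    return cfg
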