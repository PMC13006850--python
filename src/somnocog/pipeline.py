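"""End-to-end orchestration: simulate → preprocess → detect → metrics → model.

Each stage reads the outputs of the previous one from disk, so any stage can
be re-run from cached upstream results. A run manifest records the config
hash, seeds, per-stage row counts (nights in / excluded, events detected,
days modelled) and the package version; identical config and seed give
byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import load_config
from .detect import SOParams, SpindleParams, detect_slow_oscillations, detect_spindles
from .edfio import read_edf, read_hypnogram, write_edf, write_events, write_hypnogram
from .metrics import apply_exclusions, night_metrics_row
from .preprocess import build_analysis_mask, fir_bandpass, select_best_channel
from .stats import fit_glmm, robust_z_outliers
from .synthetic import (
    BehaviorSimSpec,
    EventInjectionSpec,
    HypnogramSpec,
    calibrated_transition_matrix,
    derive_seed,
    generate_hypnogram,
    simulate_behavior,
    synthesize_night,
)
from .types import Hypnogram


def _config_hash(cfg: dict[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulate_stage(cfg: dict[str, Any], out: Path, seed: int) -> dict[str, Any]:
    """Generate the synthetic cohort: EDFs, hypnograms, truth events, behavior."""
    sim = cfg["simulate"]
    out.mkdir(parents=True, exist_ok=True)
    P = calibrated_transition_matrix(sim["stage_target_min"], sim["stage_dwell_epochs"])
    truth_rows = []
    for i in range(sim["n_participants"]):
        pid = f"p{i:02d}"
        for j in range(sim["n_nights"]):
            hspec = HypnogramSpec(
                transition_matrix=P,
                initial_stage="W",
                n_epochs=sim["n_epochs"],
                seed=derive_seed(seed, i, j, 1),
            )
            hyp = generate_hypnogram(hspec)
            inj = EventInjectionSpec(
                so_density_per_min=sim["so_density_per_min"],
                spindle_density_per_min=sim["spindle_density_per_min"],
                so_amp_uV=sim["so_amp_uV"],
                spindle_amp_uV=sim["spindle_amp_uV"],
                spindle_freq_hz=sim["spindle_freq_hz"],
                noise_rms_uV=sim["noise_rms_uV"],
                noise_exponent=sim["noise_exponent"],
                fs=sim["fs"],
                channel=cfg["preprocess"]["candidate_channels"][0],
                seed=derive_seed(seed, i, j, 2),
            )
            night, truth = synthesize_night(hyp, inj)
            night.participant_id, night.night_id = pid, f"{pid}_n{j:02d}"
            base = out / f"{pid}_n{j:02d}"
            write_edf(base.with_suffix(".edf"), night)
            write_hypnogram(base.with_suffix(".hyp.csv"), hyp)
            write_events(base.with_suffix(".truth.csv"), truth)
            minutes = hyp.minutes_in("N2", "N3")
            from .metrics import compute_macro_metrics

            macro = compute_macro_metrics(hyp)
            truth_rows.append(
                {
                    "participant": pid,
                    "day": j,
                    "so_density": sum(e.type == "SO" for e in truth) / minutes if minutes else np.nan,
                    "spindle_density": sum(e.type == "spindle" for e in truth) / minutes if minutes else np.nan,
                    "waso_min": macro["waso_min"],
                }
            )
    predictors = pd.DataFrame(truth_rows)
    predictors.to_csv(out / "true_predictors.csv", index=False)

    beh = sim["behavior"]
    bspec = BehaviorSimSpec(
        n_participants=sim["n_participants"],
        n_days=sim["n_nights"],
        beta0=beh["beta0"],
        betas=dict(beh["betas"]),
        var_between=beh["var_between"],
        var_within=beh["var_within"],
        family=beh["family"],
        zero_inflation_prob=beh["zero_inflation_prob"],
        seed=derive_seed(seed, 9999),
    )
    behavior = simulate_behavior(bspec, predictors)
    behavior.to_csv(out / "behavior.csv", index=False)
    return {
        "nights_simulated": sim["n_participants"] * sim["n_nights"],
        "behavior_days": len(behavior),
    }


def detect_night(
    edf_path: Path, hyp_path: Path, cfg: dict[str, Any]
) -> tuple[dict[str, Any] | None, list]:
    """Preprocess and run both detectors on one night.

    Returns (metrics row or None if the night is discarded, events).
    """
    night = read_edf(edf_path)
    hyp = read_hypnogram(hyp_path)
    pp = cfg["preprocess"]
    candidates = [c for c in pp["candidate_channels"] if c in night.channel_names]
    if not candidates:
        raise ValueError(
            f"night {night.night_id}: none of the candidate channels "
            f"{pp['candidate_channels']} present (has {night.channel_names})"
        )
    ch = select_best_channel(night, candidates, pp["quality_threshold"])
    if ch is None:
        return None, []
    raw = night.channel(ch)
    filt = fir_bandpass(raw, night.fs, pp["filter"]["lo"], pp["filter"]["hi"], pp["filter"]["order"])
    mask = build_analysis_mask(night, ch, hyp, pp["reject_uV"], prefiltered=filt)
    so = detect_slow_oscillations(filt, night.fs, mask, SOParams(**cfg["so"]), hyp=hyp, channel=ch)
    sp_cfg = dict(cfg["spindle"])
    sp = detect_spindles(filt, night.fs, mask, SpindleParams(**sp_cfg), hyp=hyp, channel=ch)
    events = sorted(so + sp, key=lambda e: e.onset_s)
    night_idx = int(edf_path.stem.split("_n")[-1]) if "_n" in edf_path.stem else 0
    row = night_metrics_row(
        night.participant_id, night_idx, hyp, events, night.channel_quality[ch]
    )
    return row, events


def detect_stage(cfg: dict[str, Any], data_dir: Path, out: Path) -> dict[str, Any]:
    """Run detection over every (EDF, hypnogram) pair in ``data_dir``."""
    out.mkdir(parents=True, exist_ok=True)
    rows, discarded = [], 0
    for edf_path in sorted(data_dir.glob("*.edf")):
        hyp_path = edf_path.with_suffix(".hyp.csv")
        if not hyp_path.exists():
            raise FileNotFoundError(f"no hypnogram for {edf_path.name}")
        row, events = detect_night(edf_path, hyp_path, cfg)
        if row is None:
            discarded += 1
            continue
        write_events(out / f"{edf_path.stem}.events.csv", events)
        rows.append(row)
    nights = pd.DataFrame(rows)
    nights.to_csv(out / "night_metrics.csv", index=False)
    return {"nights_in": len(rows) + discarded, "nights_discarded_quality": discarded}


def metrics_stage(cfg: dict[str, Any], out: Path) -> dict[str, Any]:
    nights = pd.read_csv(out / "night_metrics.csv")
    retained, log = apply_exclusions(
        nights,
        min_nights=cfg["metrics"]["min_nights"],
        quality_threshold=cfg["preprocess"]["quality_threshold"],
    )
    retained.to_csv(out / "night_metrics_retained.csv", index=False)
    log.to_csv(out / "exclusions.csv", index=False)
    return {"nights_retained": len(retained), "nights_excluded": len(log)}


def model_stage(cfg: dict[str, Any], data_dir: Path, out: Path, seed: int) -> dict[str, Any]:
    """Join behavior to per-night sleep metrics and fit the configured GLMM."""
    nights = pd.read_csv(out / "night_metrics_retained.csv")
    behavior = pd.read_csv(data_dir / "behavior.csv")
    mc = cfg["model"]
    nights = nights.rename(columns={"night": "day"})
    merged = behavior[["participant", "day", "outcome"]].merge(
        nights[["participant", "day"] + [p for p in mc["predictors"] if p in nights.columns]],
        on=["participant", "day"],
        how="inner",
    )
    # flag isolated, implausibly high nightly SO densities before modelling
    if "so_density" in merged.columns:
        bad = robust_z_outliers(merged["so_density"], cfg["stats"]["so_density_outlier_z"])
        merged = merged[~bad]
    result = fit_glmm(
        merged,
        outcome=mc["outcome"],
        predictors=mc["predictors"],
        family=mc["family"],
        zero_inflated=mc["zero_inflated"],
        latent_scale=cfg["stats"]["latent_scale"],
    )
    result.fixed_effects.to_csv(out / "model_fixed_effects.csv", index=False)
    summary = {
        "formula": result.formula,
        "family": result.family,
        "var_between": result.var_between,
        "var_within": result.var_within,
        "icc": result.icc,
        "loglik": result.loglik,
    }
    (out / "model_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return {"days_modelled": len(merged), "icc": result.icc}


def run_pipeline(
    config: str | Path | dict | None, out: str | Path, seed: int = 0
) -> dict[str, Any]:
    """Execute every stage in dependency order; returns the run manifest."""
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out)
    data_dir = out / "data"
    results_dir = out / "results"
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": {},
    }
    manifest["stages"]["simulate"] = simulate_stage(cfg, data_dir, seed)
    manifest["stages"]["detect"] = detect_stage(cfg, data_dir, results_dir)
    manifest["stages"]["metrics"] = metrics_stage(cfg, results_dir)
    manifest["stages"]["model"] = model_stage(cfg, data_dir, results_dir, seed)
    manifest["inputs"] = sorted(p.name for p in data_dir.glob("*.edf"))
    s = manifest["stages"]
    if s["detect"]["nights_in"] != (
        s["metrics"]["nights_retained"] + s["metrics"]["nights_excluded"]
        + s["detect"]["nights_discarded_quality"]
    ):
        raise RuntimeError("manifest counts do not reconcile across stages")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
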