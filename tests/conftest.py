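"""Shared fixtures: calibrated chain, short synthetic nights, trial tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somnocog import (
    EventInjectionSpec,
    Hypnogram,
    HypnogramSpec,
    calibrated_transition_matrix,
    generate_hypnogram,
    synthesize_night,
)
from somnocog.config import default_config
from somnocog.preprocess import build_analysis_mask, fir_bandpass
from somnocog.synthetic import derive_seed
from somnocog.types import EEGNight

FS = 250.0


@pytest.fixture(scope="session")
def transition_matrix():
    sim = default_config()["simulate"]
    return calibrated_transition_matrix(sim["stage_target_min"], sim["stage_dwell_epochs"])


def make_night(seed: int, n_epochs: int = 240, transition_matrix=None, **inj_kwargs):
    """One synthetic night: hypnogram, EEG, truth events, filtered trace, mask."""
    sim = default_config()["simulate"]
    P = (
        transition_matrix
        if transition_matrix is not None
        else calibrated_transition_matrix(sim["stage_target_min"], sim["stage_dwell_epochs"])
    )
    hyp = generate_hypnogram(
        HypnogramSpec(P, "W", n_epochs, seed=derive_seed(seed, 1))
    )
    inj = EventInjectionSpec(seed=derive_seed(seed, 2), **inj_kwargs)
    night, truth = synthesize_night(hyp, inj)
    filt = fir_bandpass(night.signal[0], FS, 0.3, 40.0, 300)
    mask = build_analysis_mask(night, inj.channel, hyp, 200.0, prefiltered=filt)
    return hyp, night, truth, filt, mask


@pytest.fixture(scope="session")
def synthetic_night(transition_matrix):
    """One default-SNR night shared by the detection tests (seed 11)."""
    return make_night(11, transition_matrix=transition_matrix)


def quiet_night_signal(n_epochs: int = 10, noise_sd: float = 0.5, seed: int = 0):
    """Near-silent all-N2 night for hand-built event probes."""
    hyp = Hypnogram(np.array(["N2"] * n_epochs))
    n = int(n_epochs * 30 * FS)
    x = np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return hyp, x


def mask_for(x: np.ndarray, hyp: Hypnogram, reject_uV: float = 200.0):
    night = EEGNight(x[np.newaxis, :], FS, ["F7-O1"], {"F7-O1": 1.0})
    return build_analysis_mask(night, "F7-O1", hyp, reject_uV)


def match_counts(truth, detected, tol_s: float = 0.5):
    """(n_truth, n_detected, truth matched, detections matched) by onset."""
    t_on = np.array([e.onset_s for e in truth])
    d_on = np.array([e.onset_s for e in detected])
    mt = sum((np.abs(d_on - t) <= tol_s).any() for t in t_on) if d_on.size else 0
    md = sum((np.abs(t_on - d) <= tol_s).any() for d in d_on) if t_on.size else 0
    return len(truth), len(detected), mt, md


def gonogo_trials(go_rts, nogo_responses: int, n_nogo: int = 60, go_correct=None):
    """Build a Go/NoGo trial table: go trials with given RTs, nogo trials."""
    rows = []
    for i, rt in enumerate(go_rts):
        correct = True if go_correct is None else go_correct[i]
        rows.append(
            {"condition": "go", "trial_index": i, "responded": True,
             "correct": correct, "rt_ms": float(rt)}
        )
    for j in range(n_nogo):
        responded = j < nogo_responses
        rows.append(
            {"condition": "nogo", "trial_index": len(go_rts) + j,
             "responded": responded, "correct": not responded,
             "rt_ms": 500.0 if responded else np.nan}
        )
    return pd.DataFrame(rows)


def simon_trials(cells: dict[tuple[str, str], list[float]], correct=True):
    """Simon trial table from {(congruency, switch): [rt, ...]} cells."""
    rows = []
    for (congruency, switch), rts in cells.items():
        for rt in rts:
            rows.append(
                {"congruency": congruency, "switch": switch, "responded": True,
                 "correct": correct, "rt_ms": float(rt)}
            )
    return pd.DataFrame(rows)
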