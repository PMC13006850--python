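"""Per-night sleep macro/micro metrics and feasibility exclusion rules.

Macroarchitecture follows conventional definitions on the 30-s epoch grid:
stage minutes are half the epoch counts, total sleep time (TST) is the sum
of the four sleep-stage durations, wake after sleep onset (WASO) counts wake
scored between the first and last sleep epochs, awakenings are maximal wake
runs inside that span, and sleep efficiency is TST over time in bed.
Event densities divide counts by scored N2+N3 minutes (an artifact-free
denominator is available as a configuration switch). Exclusions drop nights
without a usable channel and then participants with fewer than the minimum
number of surviving nights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Hypnogram, SleepEvent


class DensityUndefinedError(ValueError):
    """Raised when a density is requested for a night with no N2+N3 sleep."""


def compute_macro_metrics(hyp: Hypnogram) -> dict[str, float]:
    """Macroarchitecture summary for one night (minutes, counts, percent)."""
    epm = hyp.epoch_len_s / 60.0  # minutes per epoch
    out = {
        "n1_min": hyp.minutes_in("N1"),
        "n2_min": hyp.minutes_in("N2"),
        "n3_min": hyp.minutes_in("N3"),
        "rem_min": hyp.minutes_in("REM"),
    }
    out["tst_min"] = out["n1_min"] + out["n2_min"] + out["n3_min"] + out["rem_min"]

    asleep = hyp.is_stage("N1", "N2", "N3", "REM")
    if not asleep.any():
        out.update({"waso_min": 0.0, "n_awakenings": 0, "sleep_efficiency": 0.0})
        return out
    first, last = np.where(asleep)[0][[0, -1]]
    span_wake = ~asleep[first : last + 1]
    out["waso_min"] = float(span_wake.sum()) * epm
    # maximal wake runs within the sleep span
    padded = np.concatenate([[False], span_wake, [False]])
    out["n_awakenings"] = int(np.sum(~padded[:-1] & padded[1:]))
    tib_min = hyp.n_epochs * epm  # time in bed: first to last epoch on record
    out["sleep_efficiency"] = 100.0 * out["tst_min"] / tib_min
    return out


def compute_density(
    events: list[SleepEvent],
    hyp: Hypnogram,
    kind: str,
    usable_minutes: float | None = None,
) -> float:
    """Events of ``kind`` per minute of N2+N3 sleep.

    By default the denominator is scored N2+N3 stage minutes; pass
    ``usable_minutes`` to use the artifact-free variant instead.
    """
    if kind not in ("SO", "spindle"):
        raise ValueError(f"unknown event kind {kind!r}")
    denom = usable_minutes if usable_minutes is not None else hyp.minutes_in("N2", "N3")
    if denom <= 0:
        raise DensityUndefinedError("no N2+N3 minutes; density undefined, exclude the night")
    count = sum(1 for e in events if e.type == kind)
    return count / denom


def night_metrics_row(
    participant_id: str,
    night_index: int,
    hyp: Hypnogram,
    events: list[SleepEvent],
    best_quality: float,
) -> dict[str, float]:
    """Assemble one tidy NightMetrics row (macro + micro + quality)."""
    row: dict[str, float] = {"participant": participant_id, "night": night_index}
    row.update(compute_macro_metrics(hyp))
    sos = [e for e in events if e.type == "SO"]
    sps_ = [e for e in events if e.type == "spindle"]
    has_n2n3 = hyp.minutes_in("N2", "N3") > 0
    row["so_density"] = compute_density(events, hyp, "SO") if has_n2n3 else np.nan
    row["spindle_density"] = compute_density(events, hyp, "spindle") if has_n2n3 else np.nan
    row["so_amp_uV"] = float(np.mean([e.p2p_uV for e in sos])) if sos else np.nan
    row["spindle_dur_s"] = float(np.mean([e.duration_s for e in sps_])) if sps_ else np.nan
    row["spindle_amp_uV"] = float(np.mean([e.env_amp_uV for e in sps_])) if sps_ else np.nan
    row["best_quality"] = best_quality
    return row


def apply_exclusions(
    nights: pd.DataFrame,
    min_nights: int = 4,
    quality_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Night- then participant-level feasibility exclusions.

    ``nights`` is tidy with columns participant, night, best_quality (the
    best candidate-channel quality for the night). First drops nights whose
    best quality falls below the threshold, then drops participants left
    with fewer than ``min_nights`` nights. Returns (retained, exclusion_log);
    the log has one row per excluded night with a reason code.
    """
    if nights.empty:
        return nights.copy(), pd.DataFrame(columns=["participant", "night", "reason"])
    log_rows = []
    poor = nights["best_quality"] < quality_threshold
    for row in nights[poor].itertuples(index=False):
        log_rows.append({"participant": row.participant, "night": row.night, "reason": "channel_quality"})
    kept = nights[~poor]
    counts = kept.groupby("participant")["night"].count()
    few = set(counts[counts < min_nights].index)
    for row in kept[kept["participant"].isin(few)].itertuples(index=False):
        log_rows.append({"participant": row.participant, "night": row.night, "reason": "too_few_nights"})
    retained = kept[~kept["participant"].isin(few)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["participant", "night", "reason"])
    return retained, log
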