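"""Scoring of daily Go/NoGo and Simon-switch sessions.

Trial tables are tidy DataFrames, one row per trial. Go/NoGo trials carry a
``condition`` of ``go``/``nogo``; Simon trials carry ``congruency``
(``congruent``/``incongruent``) and ``switch`` (``switch``/``nonswitch``/
``first`` for the first trial of a block, which carries no switch label).
``responded`` and ``correct`` are booleans; ``rt_ms`` is present iff the
participant responded.

Reaction-time outlier bounds are strict ("below"/"above"): 200-900 ms for
Go/NoGo and 300-3000 ms for the Simon task, boundary values kept. Missing
outcomes (an empty required cell, or no valid go reaction times) are
reported as NaN so the day can be dropped from the relevant models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GONOGO_RT_BOUNDS_MS = (200.0, 900.0)
SIMON_RT_BOUNDS_MS = (300.0, 3000.0)


def _valid_rt(df: pd.DataFrame, bounds: tuple[float, float]) -> pd.Series:
    rt = df["rt_ms"]
    return df["responded"] & rt.notna() & (rt >= bounds[0]) & (rt <= bounds[1])


def score_gonogo(
    trials: pd.DataFrame,
    rt_bounds_ms: tuple[float, float] = GONOGO_RT_BOUNDS_MS,
    commission_denominator: str = "all_nogo",
) -> dict[str, float]:
    """Go/NoGo outcomes: mean go RT, hit rate, commission-error rate.

    ``commission_denominator`` selects what the commission count is divided
    by: every no-go trial (``all_nogo``, default) or the number of correct
    go responses (``correct_go``).
    """
    go = trials[trials["condition"] == "go"]
    nogo = trials[trials["condition"] == "nogo"]
    if go.empty or nogo.empty:
        raise ValueError("session needs at least one go and one nogo trial")

    correct_go = go[go["correct"] & go["responded"]]
    rt_ok = correct_go[_valid_rt(correct_go, rt_bounds_ms)]
    gng_rt = float(rt_ok["rt_ms"].mean()) if len(rt_ok) else np.nan

    hit_pct = 100.0 * len(correct_go) / len(go)
    n_commission = int(nogo["responded"].sum())
    if commission_denominator == "all_nogo":
        denom = len(nogo)
    elif commission_denominator == "correct_go":
        denom = len(correct_go)
    else:
        raise ValueError(f"unknown commission denominator {commission_denominator!r}")
    commission_pct = 100.0 * n_commission / denom if denom else np.nan

    return {"gng_rt_ms": gng_rt, "gng_hit_pct": hit_pct, "commission_pct": commission_pct}


def _cell_mean_rt(df: pd.DataFrame, bounds, correct_only: bool) -> float:
    sel = df[_valid_rt(df, bounds)]
    if correct_only:
        sel = sel[sel["correct"]]
    return float(sel["rt_ms"].mean()) if len(sel) else np.nan


def _cell_acc(df: pd.DataFrame) -> float:
    return 100.0 * float(df["correct"].mean()) if len(df) else np.nan


def score_simon_switch(
    trials: pd.DataFrame,
    rt_bounds_ms: tuple[float, float] = SIMON_RT_BOUNDS_MS,
    correct_only: bool = True,
    accuracy_sign: str = "table",
) -> dict[str, float]:
    """Simon and switch effects on reaction time and accuracy.

    RT effects: mean(incongruent) - mean(congruent) and
    mean(switch) - mean(nonswitch); cells use responded trials within the
    outlier bounds, restricted to correct responses by default.

    Accuracy effects with ``accuracy_sign="table"`` (default) are oriented so
    an interference cost is negative: incongruent-minus-congruent for the
    Simon effect, nonswitch-minus-switch... i.e. non-switch advantage
    positive for the switch effect. ``accuracy_sign="literal"`` flips the
    Simon accuracy orientation to congruent-minus-incongruent.
    """
    cong = trials[trials["congruency"] == "congruent"]
    incong = trials[trials["congruency"] == "incongruent"]
    sw = trials[trials["switch"] == "switch"]
    nsw = trials[trials["switch"] == "nonswitch"]

    rt_cong = _cell_mean_rt(cong, rt_bounds_ms, correct_only)
    rt_incong = _cell_mean_rt(incong, rt_bounds_ms, correct_only)
    rt_sw = _cell_mean_rt(sw, rt_bounds_ms, correct_only)
    rt_nsw = _cell_mean_rt(nsw, rt_bounds_ms, correct_only)

    acc_cong, acc_incong = _cell_acc(cong), _cell_acc(incong)
    acc_sw, acc_nsw = _cell_acc(sw), _cell_acc(nsw)

    simon_acc = acc_incong - acc_cong
    if accuracy_sign == "literal":
        simon_acc = -simon_acc
    elif accuracy_sign != "table":
        raise ValueError(f"unknown accuracy sign convention {accuracy_sign!r}")

    return {
        "simon_effect_rt_ms": rt_incong - rt_cong,
        "simon_effect_acc_pct": simon_acc,
        "switch_effect_rt_ms": rt_sw - rt_nsw,
        "switch_effect_acc_pct": acc_nsw - acc_sw,
        "congruent_rt_ms": rt_cong,
        "incongruent_rt_ms": rt_incong,
    }


def score_session(
    participant_id: str,
    day_index: int,
    gonogo_trials: pd.DataFrame | None = None,
    simon_trials: pd.DataFrame | None = None,
    **kwargs,
) -> dict[str, float]:
    """One tidy SessionScores row from a day's trial logs."""
    row: dict[str, float] = {"participant": participant_id, "day": day_index}
    if gonogo_trials is not None:
        row.update(score_gonogo(gonogo_trials, **{k: v for k, v in kwargs.items() if k in ("rt_bounds_ms", "commission_denominator")}))
    if simon_trials is not None:
        row.update(score_simon_switch(simon_trials))
    return row
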