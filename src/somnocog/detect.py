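"""Slow-oscillation and sleep-spindle detection on masked N2/N3 sleep.

Slow oscillations are found on the 0.3-4 Hz trace as a negative half-wave
followed by a positive half-wave between interpolated zero crossings, and
kept when the negative peak reaches 33 μV, the trough-to-peak amplitude
reaches 61 μV, the negative half-wave lasts 125-1500 ms, and the positive
half-wave at most 1000 ms.

Spindles use a sliding-window sigma-feature detector: on 0.3-s windows
stepped by 0.1 s, relative sigma power (11-16 Hz over 0.4-30 Hz broadband),
the Pearson correlation between the sigma-filtered and broadband signals,
and the sigma-broadband covariance (log-scaled, z-scored against a 30-s
moving baseline) must all exceed their thresholds; runs of consecutive
positive windows merge into candidates kept when 0.5-2.5 s long. The
absolute-sigma-power criterion of the original four-feature detector is
deliberately omitted, reflecting a non-standard frontal-occipital montage.

Both detectors return only events wholly inside artifact-free N2/N3 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .preprocess import fir_bandpass
from .types import AnalysisMask, Hypnogram, SleepEvent


@dataclass
class SOParams:
    """Amplitude/duration criteria for slow-oscillation acceptance."""

    bp_lo: float = 0.3
    bp_hi: float = 4.0
    neg_amp_uV: float = 33.0
    p2p_amp_uV: float = 61.0
    neg_dur_min_ms: float = 125.0
    neg_dur_max_ms: float = 1500.0
    pos_dur_max_ms: float = 1000.0
    # the 0.3-4 Hz detection band uses a zero-phase Butterworth: a short FIR
    # would attenuate the passband itself (~20% at 1 Hz), biasing the
    # amplitude criteria; an IIR has unit passband gain at any order
    butter_order: int = 4

    def __post_init__(self) -> None:
        vals = [self.neg_amp_uV, self.p2p_amp_uV, self.neg_dur_min_ms,
                self.neg_dur_max_ms, self.pos_dur_max_ms]
        if any(v <= 0 for v in vals):
            raise ValueError("all slow-oscillation criteria must be positive")
        if self.neg_dur_min_ms >= self.neg_dur_max_ms:
            raise ValueError("negative-duration bounds out of order")


@dataclass
class SpindleParams:
    """Sliding-window sigma-feature thresholds and admissible durations."""

    sigma_lo: float = 11.0
    sigma_hi: float = 16.0
    broad_lo: float = 0.4
    broad_hi: float = 30.0
    win_s: float = 0.3
    step_s: float = 0.1
    thr_relpow: float = 1.6   # z of log10 relative sigma power vs baseline
    thr_corr: float = 0.69
    thr_cov: float = 1.3       # z of log10 covariance vs the moving baseline
    dur_min_s: float = 0.5
    dur_max_s: float = 2.5
    baseline_s: float = 30.0   # moving-baseline span for covariance z-scoring
    filter_order: int = 300

    def __post_init__(self) -> None:
        if not self.dur_min_s < self.dur_max_s:
            raise ValueError("duration bounds out of order")
        if not self.win_s > self.step_s > 0:
            raise ValueError("window must exceed step, both positive")


def _so_band(x: np.ndarray, fs: float, p: SOParams) -> np.ndarray:
    sos = sps.butter(p.butter_order, [p.bp_lo, p.bp_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _zero_crossings(xf: np.ndarray, fs: float):
    """Interpolated crossing times and directions of the sign of ``xf``.

    Returns (times_s, direction) where direction +1 means negative→positive.
    Samples exactly at zero are treated as belonging to the following
    excursion (strictly monotone crossing times).
    """
    s = np.sign(xf)
    # propagate sign over exact zeros so flat zero spans don't double-count
    nz = s != 0
    if not nz.any():
        return np.empty(0), np.empty(0, dtype=int)
    idx = np.where(nz, np.arange(s.size), 0)
    np.maximum.accumulate(idx, out=idx)
    s_f = s[idx]
    change = np.where(s_f[1:] != s_f[:-1])[0]
    times, direction = [], []
    for i in change:
        x0, x1 = xf[i], xf[i + 1]
        frac = 0.0 if x1 == x0 else x0 / (x0 - x1)
        times.append((i + frac) / fs)
        direction.append(1 if s_f[i + 1] > 0 else -1)
    return np.asarray(times), np.asarray(direction, dtype=int)


def detect_slow_oscillations(
    x: np.ndarray,
    fs: float,
    mask: AnalysisMask,
    p: SOParams | None = None,
    hyp: Hypnogram | None = None,
    channel: str = "",
) -> list[SleepEvent]:
    """Detect slow oscillations on a (0.3-40 Hz pre-filtered) trace.

    The 0.3-4 Hz bandpass is applied internally. Candidates are
    negative-then-positive half-wave pairs delimited by zero crossings;
    events must lie wholly inside usable epochs. Returned sorted by onset and
    non-overlapping by construction.
    """
    p = p or SOParams()
    if not mask.usable.any():
        return []
    xf = _so_band(x, fs, p)
    times, direction = _zero_crossings(xf, fs)
    events: list[SleepEvent] = []
    # down-crossing t0, up-crossing t1 (negative half-wave), down-crossing t2
    for j in range(len(times) - 2):
        if direction[j] != -1:
            continue
        t0, t1, t2 = times[j], times[j + 1], times[j + 2]
        neg_dur_ms = (t1 - t0) * 1000.0
        pos_dur_ms = (t2 - t1) * 1000.0
        if not p.neg_dur_min_ms <= neg_dur_ms <= p.neg_dur_max_ms:
            continue
        if pos_dur_ms > p.pos_dur_max_ms:
            continue
        i0, i1, i2 = (int(np.ceil(t * fs)) for t in (t0, t1, t2))
        if i1 <= i0 or i2 <= i1 or i2 > xf.size:
            continue
        neg_peak = float(xf[i0:i1].min())
        pos_peak = float(xf[i1:i2].max())
        if -neg_peak < p.neg_amp_uV:
            continue
        p2p = pos_peak - neg_peak
        if p2p < p.p2p_amp_uV:
            continue
        if not mask.contains_interval(t0, t2 - t0):
            continue
        events.append(
            SleepEvent(
                type="SO",
                onset_s=float(t0),
                duration_s=float(t2 - t0),
                channel=channel,
                p2p_uV=p2p,
                stage_at_onset=hyp.stage_at(t0) if hyp is not None else "",
            )
        )
    return events


def _sigma_features(x: np.ndarray, fs: float, p: SpindleParams):
    """Per-window (relative power, correlation, covariance z) features.

    Returns window start indices (samples) and the three feature arrays.
    """
    win = int(round(p.win_s * fs))
    step = int(round(p.step_s * fs))
    if win > x.size:
        raise ValueError(f"{p.win_s}-s window longer than {x.size / fs:.1f}-s signal")
    sigma = fir_bandpass(x, fs, p.sigma_lo, p.sigma_hi, p.filter_order)
    broad = fir_bandpass(x, fs, p.broad_lo, p.broad_hi, p.filter_order)

    starts = np.arange(0, x.size - win + 1, step)
    n_win = starts.size
    # windowed views: (n_win, win)
    sw = np.lib.stride_tricks.sliding_window_view(sigma, win)[::step][:n_win]
    bw = np.lib.stride_tricks.sliding_window_view(broad, win)[::step][:n_win]

    sp = np.sum(sw * sw, axis=1)
    bp = np.sum(bw * bw, axis=1)
    ratio = np.divide(sp, np.maximum(bp, 1e-12), out=np.zeros(n_win), where=bp > 0)

    sc = sw - sw.mean(axis=1, keepdims=True)
    bc = bw - bw.mean(axis=1, keepdims=True)
    cov = np.sum(sc * bc, axis=1) / win
    denom = np.sqrt(np.sum(sc * sc, axis=1) * np.sum(bc * bc, axis=1))
    corr = np.divide(np.sum(sc * bc, axis=1), denom, out=np.zeros(n_win), where=denom > 0)

    def moving_z(f: np.ndarray) -> np.ndarray:
        span = max(int(round(p.baseline_s / p.step_s)), 3)
        mu = uniform_filter1d(f, span, mode="nearest")
        m2 = uniform_filter1d(f**2, span, mode="nearest")
        sd = np.sqrt(np.maximum(m2 - mu**2, 1e-12))
        return (f - mu) / sd

    # relative power and covariance on a log scale, z-scored against the
    # moving 30-s baseline (the sliding-feature algorithm's convention); the
    # 0.1 μV² covariance floor keeps rare negative-covariance windows from
    # blowing up the baseline variance (amplitudes in physical μV throughout)
    relpow_z = moving_z(np.log10(np.maximum(ratio, 1e-12)))
    covz = moving_z(np.log10(np.maximum(cov, 0.1)))
    return starts, relpow_z, corr, covz, sigma


def detect_spindles(
    x: np.ndarray,
    fs: float,
    mask: AnalysisMask,
    p: SpindleParams | None = None,
    hyp: Hypnogram | None = None,
    channel: str = "",
) -> list[SleepEvent]:
    """Detect sigma-band spindle bursts via the three-feature sliding window.

    A window is spindle-positive iff relative sigma power, sigma-broadband
    correlation, and covariance-z all exceed their thresholds; consecutive
    positive windows merge (no bridging across gaps of a step or more) and
    merged candidates are kept iff 0.5-2.5 s long and inside usable epochs.
    ``env_amp_uV`` is the mean sigma-envelope (analytic-signal magnitude)
    over the event.
    """
    p = p or SpindleParams()
    if not mask.usable.any():
        return []
    starts, relpow, corr, covz, sigma = _sigma_features(x, fs, p)
    positive = (relpow > p.thr_relpow) & (corr > p.thr_corr) & (covz > p.thr_cov)
    if not positive.any():
        return []
    envelope = np.abs(sps.hilbert(sigma))
    win = int(round(p.win_s * fs))

    events: list[SleepEvent] = []
    idx = np.where(positive)[0]
    run_start = idx[0]
    prev = idx[0]
    runs = []
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append((run_start, prev))
        run_start = prev = i
    runs.append((run_start, prev))

    for a, b in runs:
        s0 = starts[a]
        s1 = starts[b] + win
        onset = s0 / fs
        dur = (s1 - s0) / fs
        if not p.dur_min_s <= dur <= p.dur_max_s:
            continue
        if not mask.contains_interval(onset, dur):
            continue
        events.append(
            SleepEvent(
                type="spindle",
                onset_s=float(onset),
                duration_s=float(dur),
                channel=channel,
                env_amp_uV=float(envelope[s0:s1].mean()),
                stage_at_onset=hyp.stage_at(onset) if hyp is not None else "",
            )
        )
    return events


def summarize_event_shapes(
    events: list[SleepEvent],
    x: np.ndarray,
    fs: float,
    half_win_s: float = 2.0,
    so_params: SOParams | None = None,
    spindle_params: SpindleParams | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Time-locked averages around detections: SO waveform, spindle envelope.

    The anchor is the negative peak (slow oscillations, 0.3-4 Hz trace) or
    the sigma-envelope maximum (spindles). Returns, per event type present,
    a dict with keys ``t`` (s, anchor at 0), ``mean``, ``sem`` and ``n``.
    """
    if not events:
        raise ValueError("cannot summarize an empty event list")
    so_params = so_params or SOParams()
    spindle_params = spindle_params or SpindleParams()
    hw = int(round(half_win_s * fs))
    out: dict[str, dict[str, np.ndarray]] = {}

    by_type: dict[str, list[SleepEvent]] = {}
    for e in events:
        by_type.setdefault(e.type, []).append(e)

    for etype, evs in by_type.items():
        if etype == "SO":
            trace = _so_band(x, fs, so_params)
            pick = np.argmin
        else:
            sigma = fir_bandpass(
                x, fs, spindle_params.sigma_lo, spindle_params.sigma_hi, spindle_params.filter_order
            )
            trace = np.abs(sps.hilbert(sigma))
            pick = np.argmax
        snippets = []
        for e in evs:
            i0 = int(round(e.onset_s * fs))
            i1 = int(round((e.onset_s + e.duration_s) * fs))
            i0, i1 = max(i0, 0), min(i1, trace.size)
            if i1 <= i0:
                continue
            anchor = i0 + int(pick(trace[i0:i1]))
            if anchor - hw < 0 or anchor + hw + 1 > trace.size:
                continue
            snippets.append(trace[anchor - hw : anchor + hw + 1])
        if not snippets:
            continue
        arr = np.vstack(snippets)
        out[etype] = {
            "t": (np.arange(-hw, hw + 1)) / fs,
            "mean": arr.mean(axis=0),
            "sem": arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(arr.shape[1]),
            "n": np.array(arr.shape[0]),
        }
    if not out:
        raise ValueError("no event fit inside the signal with the requested window")
    return out
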