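"""Synthetic multi-night sleep-EEG and behavior generator.

Everything the downstream pipeline consumes can be generated here with known
ground truth: Markov-chain hypnograms calibrated to a realistic older-adult
stage profile, 250 Hz EEG made of 1/f background plus injected slow
oscillations and sigma-band spindle bursts confined to N2/N3, and
participant-by-day behavioral outcomes drawn from a random-intercept mixed
model with configurable variance components. Detection and inference can
then be validated by recovery against the injected truth.

Determinism: every public operation takes an integer seed; one global seed
fans out to per-night subseeds through a splitmix-style hash so nights are
mutually independent yet exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import expit

from .types import EPOCH_LEN_S, STAGES, EEGNight, Hypnogram, SleepEvent


class GenerationError(RuntimeError):
    """Raised when a requested synthesis is infeasible (e.g. event density
    too high to place without overlap)."""


def derive_seed(seed: int, *streams: int) -> int:
    """Fan a global seed out to an independent substream (splitmix64-style).

    Returns a value below 2**31 so it is safe for any RNG constructor.
    """
    mask = (1 << 64) - 1
    z = int(seed) & mask
    for s in streams:
        z = (z + 0x9E3779B97F4A7C15 * (int(s) + 1)) & mask
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z = z ^ (z >> 31)
    return z % 2**31


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

@dataclass
class HypnogramSpec:
    """Markov-chain specification for one night's stage sequence."""

    transition_matrix: np.ndarray
    initial_stage: str = "W"
    n_epochs: int = 931
    epoch_len_s: float = EPOCH_LEN_S
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (len(STAGES), len(STAGES)):
            raise ValueError(f"transition matrix must be {len(STAGES)}x{len(STAGES)}")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each transition row must be non-negative and sum to 1")
        if self.n_epochs <= 0:
            raise ValueError("n_epochs must be positive")
        if self.initial_stage not in STAGES:
            raise ValueError(f"unknown initial stage {self.initial_stage!r}")
        self.transition_matrix = P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a stochastic matrix via eigen-decomposition."""
    vals, vecs = np.linalg.eig(np.asarray(P, dtype=float).T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def calibrated_transition_matrix(
    stage_target_min: dict[str, float],
    stage_dwell_epochs: dict[str, float],
    tol: float = 1e-12,
    max_iter: int = 500,
) -> np.ndarray:
    """Build a stage-transition matrix with prescribed stationary profile.

    The self-transition of stage *i* is fixed by its mean bout length
    (``P_ii = 1 - 1/L_i``, geometric dwell) and the off-diagonal mass is
    distributed so the chain's stationary distribution matches the target
    stage-minute profile. The off-diagonal weights are found by fixed-point
    iteration on the stationary distribution.
    """
    pi_t = np.array([stage_target_min[s] for s in STAGES], dtype=float)
    if np.any(pi_t < 0) or pi_t.sum() <= 0:
        raise ValueError("stage targets must be non-negative with positive total")
    pi_t = pi_t / pi_t.sum()
    L = np.array([stage_dwell_epochs[s] for s in STAGES], dtype=float)
    if np.any(L < 1.0):
        raise ValueError("mean dwell must be at least one epoch")

    def build(pi: np.ndarray) -> np.ndarray:
        w = pi / L
        P = np.zeros((len(STAGES), len(STAGES)))
        for i in range(len(STAGES)):
            off = w.copy()
            off[i] = 0.0
            off = off / off.sum()
            P[i] = off / L[i]
            P[i, i] = 1.0 - 1.0 / L[i]
        return P

    pi = pi_t.copy()
    for _ in range(max_iter):
        P = build(pi)
        s = stationary_distribution(P)
        err = np.max(np.abs(s - pi_t))
        if err < tol:
            break
        pi = pi * (pi_t / np.maximum(s, 1e-300))
        pi = pi / pi.sum()
    # exact row normalisation against floating-point drift
    P = P / P.sum(axis=1, keepdims=True)
    return P


def generate_hypnogram(spec: HypnogramSpec) -> Hypnogram:
    """Draw one night's stage sequence from the Markov chain in ``spec``."""
    rng = np.random.default_rng(spec.seed)
    P = spec.transition_matrix
    cum = np.cumsum(P, axis=1)
    state = STAGES.index(spec.initial_stage)
    out = np.empty(spec.n_epochs, dtype="U4")
    u = rng.random(spec.n_epochs)
    for k in range(spec.n_epochs):
        out[k] = STAGES[state]
        state = int(np.searchsorted(cum[state], u[k], side="right"))
        state = min(state, len(STAGES) - 1)
    return Hypnogram(out, epoch_len_s=spec.epoch_len_s)


# ---------------------------------------------------------------------------
# EEG synthesis with injected events
# ---------------------------------------------------------------------------

@dataclass
class EventInjectionSpec:
    """Event rates, amplitudes and background-noise model for one night."""

    so_density_per_min: float = 4.2
    spindle_density_per_min: float = 1.52
    # raw (device-level) peak-to-peak; the acquisition-style 0.3-40 Hz
    # 300-order FIR attenuates ~1 Hz content by ~30%, so a 120 μV raw wave
    # measures near the observed ~86 μV scale on the detection trace
    so_amp_uV: float = 120.0
    spindle_amp_uV: float = 20.0      # peak of the Hann-windowed burst
    spindle_freq_hz: float = 13.0
    spindle_dur_s: tuple[float, float] = (0.7, 1.1)
    noise_rms_uV: float = 15.0
    noise_exponent: float = 1.0       # power ∝ 1/f**exponent
    n3_delta_rms_uV: float = 5.0      # extra 0.5–2 Hz power in N3
    fs: float = 250.0
    channel: str = "F7-O1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.so_density_per_min < 0 or self.spindle_density_per_min < 0:
            raise ValueError("event densities must be non-negative")
        if not 11.0 <= self.spindle_freq_hz <= 16.0:
            raise ValueError("spindle frequency must lie in the 11-16 Hz sigma band")
        lo, hi = self.spindle_dur_s
        if not 0 < lo <= hi:
            raise ValueError("spindle duration range out of order")


def _pink_noise(n: int, fs: float, rms: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ∝ 1/f**exponent, scaled to ``rms``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _so_template(fs: float, neg_amp: float, pos_amp: float, neg_dur_s: float, pos_dur_s: float) -> np.ndarray:
    """One negative then one positive half-sine, in μV."""
    n_neg = max(int(round(neg_dur_s * fs)), 2)
    n_pos = max(int(round(pos_dur_s * fs)), 2)
    neg = -neg_amp * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = pos_amp * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def _spindle_template(fs: float, amp: float, freq: float, dur_s: float, phase: float) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 2)
    t = np.arange(n) / fs
    return amp * np.hanning(n) * np.sin(2 * np.pi * freq * t + phase)


def _eligible_runs(hyp: Hypnogram, fs: float, n_samples: int) -> list[tuple[int, int]]:
    """Contiguous N2/N3 sample spans [start, stop) clipped to the signal."""
    mask = hyp.is_stage("N2", "N3")
    runs: list[tuple[int, int]] = []
    k = 0
    spe = int(round(hyp.epoch_len_s * fs))  # samples per epoch
    while k < hyp.n_epochs:
        if mask[k]:
            k0 = k
            while k < hyp.n_epochs and mask[k]:
                k += 1
            a, b = k0 * spe, min(k * spe, n_samples)
            if b > a:
                runs.append((a, b))
        else:
            k += 1
    return runs


def synthesize_night(
    hyp: Hypnogram, inj: EventInjectionSpec
) -> tuple[EEGNight, list[SleepEvent]]:
    """Render one night of EEG for ``hyp`` with ground-truth injected events.

    Events are placed uniformly over eligible N2/N3 samples with rejection on
    overlap (a small guard gap keeps neighbours separable) and strictly inside
    contiguous N2/N3 spans, so every injected event is recoverable in
    principle. Returns the signal and the exact injected-event list.
    """
    fs = inj.fs
    rng = np.random.default_rng(inj.seed)
    n = int(round(hyp.duration_s * fs))
    x = _pink_noise(n, fs, inj.noise_rms_uV, inj.noise_exponent, rng)

    # stage-dependent slow-wave background: extra delta power in N3, faded in
    # and out over ~2 s so stage boundaries do not introduce steps
    if inj.n3_delta_rms_uV > 0 and hyp.is_stage("N3").any():
        delta = _pink_noise(n, fs, 1.0, 0.0, rng)
        sos = sps.butter(4, [0.5, 2.0], btype="bandpass", fs=fs, output="sos")
        delta = sps.sosfiltfilt(sos, delta)
        delta *= inj.n3_delta_rms_uV / max(delta.std(), 1e-12)
        spe = int(round(hyp.epoch_len_s * fs))
        gain = np.repeat(hyp.is_stage("N3").astype(float), spe)[:n]
        ramp = int(2.0 * fs)
        gain = np.convolve(gain, np.hanning(ramp) / (np.hanning(ramp).sum()), mode="same")
        x = x + delta * gain

    runs = _eligible_runs(hyp, fs, n)
    minutes_n2n3 = hyp.minutes_in("N2", "N3")
    events: list[SleepEvent] = []

    guard = int(round(0.25 * fs))  # min gap between injected events, samples
    occupied: list[tuple[int, int]] = []

    def place(template: np.ndarray) -> int:
        """Pick a non-overlapping onset for ``template``; return sample index."""
        m = len(template)
        candidates = [(a, b) for a, b in runs if b - a > m + 2 * guard]
        if not candidates:
            raise GenerationError(
                f"no contiguous N2/N3 span can hold a {m / fs:.2f}-s event "
                f"({len(runs)} spans, {minutes_n2n3:.1f} min N2+N3 available)"
            )
        weights = np.array([b - a - m - 2 * guard for a, b in candidates], dtype=float)
        for _ in range(200):
            ri = rng.choice(len(candidates), p=weights / weights.sum())
            a, b = candidates[ri]
            s0 = int(rng.integers(a + guard, b - m - guard))
            if all(s0 + m + guard <= o0 or s0 >= o1 + guard for o0, o1 in occupied):
                occupied.append((s0, s0 + m))
                return s0
        raise GenerationError(
            f"could not place event without overlap after 200 attempts; "
            f"requested density too high for {minutes_n2n3:.1f} min of N2+N3"
        )

    n_so = rng.poisson(inj.so_density_per_min * minutes_n2n3) if minutes_n2n3 > 0 else 0
    n_sp = rng.poisson(inj.spindle_density_per_min * minutes_n2n3) if minutes_n2n3 > 0 else 0

    for _ in range(n_so):
        p2p = inj.so_amp_uV * float(np.exp(rng.normal(0.0, 0.08)))
        neg_amp = 0.55 * p2p
        pos_amp = p2p - neg_amp
        neg_dur = float(rng.uniform(0.4, 0.7))
        pos_dur = float(rng.uniform(0.4, 0.7))
        tmpl = _so_template(fs, neg_amp, pos_amp, neg_dur, pos_dur)
        s0 = place(tmpl)
        x[s0 : s0 + len(tmpl)] += tmpl
        events.append(
            SleepEvent(
                type="SO",
                onset_s=s0 / fs,
                duration_s=len(tmpl) / fs,
                channel=inj.channel,
                p2p_uV=p2p,
                stage_at_onset=hyp.stage_at(s0 / fs),
            )
        )

    for _ in range(n_sp):
        dur = float(rng.uniform(*inj.spindle_dur_s))
        freq = float(np.clip(rng.normal(inj.spindle_freq_hz, 0.4), 11.0, 16.0))
        tmpl = _spindle_template(fs, inj.spindle_amp_uV, freq, dur, rng.uniform(0, 2 * np.pi))
        s0 = place(tmpl)
        x[s0 : s0 + len(tmpl)] += tmpl
        events.append(
            SleepEvent(
                type="spindle",
                onset_s=s0 / fs,
                duration_s=dur,
                channel=inj.channel,
                env_amp_uV=inj.spindle_amp_uV / 2.0,  # mean Hann envelope
                stage_at_onset=hyp.stage_at(s0 / fs),
            )
        )

    events.sort(key=lambda e: e.onset_s)
    night = EEGNight(
        signal=x[np.newaxis, :],
        fs=fs,
        channel_names=[inj.channel],
        channel_quality={inj.channel: 1.0},
    )
    return night, events


# ---------------------------------------------------------------------------
# behavioral outcomes from a random-intercept mixed model
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimSpec:
    """Participant-day outcome generator with known mixed-model structure.

    Gaussian family: ``y = beta0 + Σ beta·x + u_i + ε`` with
    ``u_i ~ N(0, var_between)`` and ``ε ~ N(0, var_within)``.

    Beta family: the same linear predictor on the logit scale gives the
    conditional mean; ``var_within`` then plays the role of the beta
    precision φ (Var(y|μ) = μ(1-μ)/(1+φ)), and an optional constant
    zero-inflation probability sets outcomes to exactly 0.
    """

    n_participants: int = 17
    n_days: int = 11
    beta0: float = 0.0
    betas: dict[str, float] = field(default_factory=dict)
    var_between: float = 0.0
    var_within: float = 0.0
    family: str = "gaussian"
    zero_inflation_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.var_between < 0 or self.var_within < 0:
            raise ValueError("variance components must be non-negative")
        if self.family not in ("gaussian", "beta"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 <= self.zero_inflation_prob <= 1.0:
            raise ValueError("zero_inflation_prob must lie in [0, 1]")


def simulate_behavior(spec: BehaviorSimSpec, sleep_predictors=None):
    """Draw participant-by-day outcomes from the random-intercept model.

    ``sleep_predictors`` is an optional tidy table (pandas DataFrame with
    columns participant, day, plus one column per predictor named in
    ``spec.betas``); when omitted, only the intercept and random effects act.
    Returns a DataFrame (participant, day, outcome, predictors...).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    participants = [f"p{i:02d}" for i in range(spec.n_participants)]

    if sleep_predictors is not None:
        df = sleep_predictors.copy()
        missing = set(spec.betas) - set(df.columns)
        if missing:
            raise ValueError(f"predictor table lacks columns: {sorted(missing)}")
        have = df.groupby("participant")["day"].count()
        if len(have) != spec.n_participants or (have != spec.n_days).any():
            raise ValueError("predictor table incomplete for the requested design")
        df = df.sort_values(["participant", "day"]).reset_index(drop=True)
    else:
        df = pd.DataFrame(
            [(p, d) for p in participants for d in range(spec.n_days)],
            columns=["participant", "day"],
        )

    u = rng.normal(0.0, np.sqrt(spec.var_between), size=spec.n_participants)
    u_map = dict(zip(sorted(df["participant"].unique()), u))
    eta = spec.beta0 + df["participant"].map(u_map).to_numpy(dtype=float)
    for name, b in spec.betas.items():
        eta = eta + b * df[name].to_numpy(dtype=float)

    if spec.family == "gaussian":
        y = eta + rng.normal(0.0, np.sqrt(spec.var_within), size=len(df))
    else:
        mu = expit(eta)
        phi = max(spec.var_within, 1e-6)
        y = rng.beta(mu * phi, (1.0 - mu) * phi)
        y = np.clip(y, 1e-12, 1.0 - 1e-12)
        if spec.zero_inflation_prob > 0:
            y = np.where(rng.random(len(df)) < spec.zero_inflation_prob, 0.0, y)

    out = df.copy()
    out["outcome"] = y
    return out
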