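"""Core domain containers shared across the pipeline.

All amplitudes are in physical microvolts (μV), all times in seconds from
recording start, and sleep staging uses the five AASM labels W, N1, N2, N3,
REM on a fixed 30-s epoch grid anchored at the start of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES: tuple[str, ...] = ("N1", "N2", "N3", "REM")
EPOCH_LEN_S: float = 30.0

#: rejection reason codes used by AnalysisMask
REASON_OK = ""
REASON_NOT_N2N3 = "not_N2N3"
REASON_AMPLITUDE = "amplitude_artifact"


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage sequence for one night.

    Parameters
    ----------
    stages
        Sequence of stage labels, one per 30-s epoch.
    epoch_len_s
        Epoch length in seconds (30 by convention).
    """

    stages: np.ndarray
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="U4")
        if self.stages.ndim != 1 or self.stages.size == 0:
            raise ValueError("hypnogram must be a non-empty 1-D stage sequence")
        bad = set(self.stages.tolist()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def is_stage(self, *labels: str) -> np.ndarray:
        """Boolean per-epoch mask for membership in ``labels``."""
        return np.isin(self.stages, labels)

    def minutes_in(self, *labels: str) -> float:
        return float(self.is_stage(*labels).sum()) * self.epoch_len_s / 60.0

    def stage_at(self, t_s: float) -> str:
        """Stage of the half-open epoch [k*30, (k+1)*30) containing ``t_s``."""
        k = int(t_s // self.epoch_len_s)
        if not 0 <= k < self.n_epochs:
            raise IndexError(f"time {t_s} s outside hypnogram")
        return str(self.stages[k])


@dataclass
class EEGNight:
    """One night of multichannel EEG plus per-channel quality metadata.

    ``signal`` is (n_channels, n_samples) in μV; ``channel_quality`` maps a
    channel name to the fraction of scoreable data in [0, 1].
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    channel_quality: dict[str, float]
    participant_id: str = "p0"
    night_id: str = "n0"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError("one row of signal per channel name required")
        for ch, q in self.channel_quality.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"channel quality for {ch} outside [0, 1]: {q}")

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.signal[i]


@dataclass
class AnalysisMask:
    """Per-epoch usability flags with rejection reason codes.

    An epoch is usable iff it is scored N2 or N3 and its demeaned trace stays
    within the amplitude-rejection threshold.
    """

    usable: np.ndarray
    reason: np.ndarray
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.usable = np.asarray(self.usable, dtype=bool)
        self.reason = np.asarray(self.reason, dtype="U24")
        if self.usable.shape != self.reason.shape:
            raise ValueError("usable and reason must align per epoch")

    @property
    def n_epochs(self) -> int:
        return int(self.usable.size)

    def usable_at(self, t_s: float) -> bool:
        k = int(t_s // self.epoch_len_s)
        return bool(0 <= k < self.n_epochs and self.usable[k])

    def contains_interval(self, onset_s: float, duration_s: float) -> bool:
        """True iff [onset, onset+duration] lies wholly inside usable epochs."""
        k0 = int(onset_s // self.epoch_len_s)
        # right-closed endpoint: an event ending exactly on an epoch boundary
        # belongs to the epoch it is leaving
        k1 = int(np.nextafter(onset_s + duration_s, 0.0) // self.epoch_len_s)
        if k0 < 0 or k1 >= self.n_epochs:
            return False
        return bool(self.usable[k0 : k1 + 1].all())


@dataclass
class SleepEvent:
    """One detected (or injected ground-truth) slow oscillation or spindle."""

    type: str  # "SO" or "spindle"
    onset_s: float
    duration_s: float
    channel: str = ""
    p2p_uV: float | None = None
    env_amp_uV: float | None = None
    stage_at_onset: str = ""

    def __post_init__(self) -> None:
        if self.type not in ("SO", "spindle"):
            raise ValueError(f"unknown event type {self.type!r}")
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class ModelResult:
    """Fitted mixed-model summary: fixed effects, variance components, ICC."""

    formula: str
    family: str
    fixed_effects: "object"  # pandas.DataFrame: estimate, se, z, p, std_estimate, ci_low, ci_high
    var_between: float
    var_within: float | None
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    type3: "object" = None  # pandas.DataFrame: F, p per predictor
    loglik: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)
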