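"""Channel selection, zero-phase FIR filtering, and the N2/N3 artifact mask.

The preprocessing chain mirrors a wearable-headband workflow: pick the best
of four frontal-occipital derivations by its scoreable-data fraction
(discard the night if none reaches the quality threshold), bandpass 0.3-40 Hz
with a 300th-order FIR applied forward-backward, cut the trace into 30-s
epochs anchored at recording start, demean each epoch, and reject epochs
whose demeaned trace exceeds 200 μV. Detection then runs only on artifact-free
N2 and N3 epochs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import (
    REASON_AMPLITUDE,
    REASON_NOT_N2N3,
    REASON_OK,
    AnalysisMask,
    EEGNight,
    Hypnogram,
)


def select_best_channel(
    night: EEGNight, candidates: list[str], quality_threshold: float = 0.5
) -> str | None:
    """Best-quality candidate channel at or above the threshold, else None.

    Ties break in candidate-list order. A None return means the night is not
    analyzable and should be discarded by the caller.
    """
    if not candidates:
        raise ValueError("candidate channel list must be non-empty")
    unknown = [c for c in candidates if c not in night.channel_quality]
    if unknown:
        raise KeyError(f"candidates without quality metadata: {unknown}")
    best, best_q = None, -1.0
    for ch in candidates:
        q = night.channel_quality[ch]
        if q > best_q:  # strict: first in order wins ties
            best, best_q = ch, q
    return best if best_q >= quality_threshold else None


def fir_bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 300) -> np.ndarray:
    """Zero-phase (forward-backward) FIR bandpass.

    ``order`` is the filter order (taps = order + 1), Hamming-windowed
    design. Forward-backward application squares the magnitude response and
    cancels the phase so event timings are not shifted.
    """
    if not 0 < lo < hi < fs / 2:
        raise ValueError("require 0 < lo < hi < Nyquist")
    if order < 2:
        raise ValueError("filter order must be at least 2")
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # keep type-I symmetry
    x = np.asarray(x, dtype=float)
    if x.size < 3 * numtaps:
        raise ValueError(
            f"signal of {x.size} samples too short for a {numtaps}-tap filter "
            f"(need at least {3 * numtaps})"
        )
    h = sps.firwin(numtaps, [lo, hi], fs=fs, pass_zero=False)
    return sps.filtfilt(h, [1.0], x)


def build_analysis_mask(
    night: EEGNight,
    channel: str,
    hyp: Hypnogram,
    reject_uV: float = 200.0,
    prefiltered: np.ndarray | None = None,
) -> AnalysisMask:
    """Per-epoch usability: N2/N3 stage and demeaned amplitude within bounds.

    The amplitude rule is evaluated on the 0.3-40 Hz filtered trace when
    ``prefiltered`` is given (the intended order of operations), else on the
    raw channel. Each 30-s epoch is demeaned independently; any
    |sample| > ``reject_uV`` rejects the epoch.
    """
    x = prefiltered if prefiltered is not None else night.channel(channel)
    spe = int(round(hyp.epoch_len_s * night.fs))
    n_full = min(hyp.n_epochs, x.size // spe)
    if hyp.n_epochs > n_full + 1:
        raise ValueError(
            f"hypnogram ({hyp.n_epochs} epochs) extends more than one epoch "
            f"beyond the signal ({x.size / night.fs:.0f} s)"
        )
    usable = np.zeros(hyp.n_epochs, dtype=bool)
    reason = np.full(hyp.n_epochs, REASON_OK, dtype="U24")
    is_n2n3 = hyp.is_stage("N2", "N3")
    for k in range(hyp.n_epochs):
        if not is_n2n3[k]:
            reason[k] = REASON_NOT_N2N3
            continue
        if k >= n_full:  # trailing partial epoch: no full data to vet
            reason[k] = REASON_AMPLITUDE
            continue
        seg = x[k * spe : (k + 1) * spe]
        if np.max(np.abs(seg - seg.mean())) > reject_uV:
            reason[k] = REASON_AMPLITUDE
        else:
            usable[k] = True
    return AnalysisMask(usable=usable, reason=reason, epoch_len_s=hyp.epoch_len_s)
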