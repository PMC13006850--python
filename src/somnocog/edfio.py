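"""Reading and writing the pipeline's on-disk formats.

EDF reading goes through MNE. Writing uses a minimal EDF encoder (16-bit,
physical units μV, 1-s data records) sufficient for round-tripping synthetic
nights; per-channel quality, which EDF has no field for, travels in a JSON
sidecar next to the recording. Hypnograms, events and behavioral tables are
plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EEGNight, Hypnogram, SleepEvent


def _pad_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def write_edf(path: str | Path, night: EEGNight) -> None:
    """Write ``night`` as 16-bit EDF with 1-second data records.

    The signal is truncated to a whole number of records; physical range is
    chosen per channel to cover the data symmetrically.
    """
    path = Path(path)
    fs = night.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = night.n_samples // spr
    if n_rec < 1:
        raise ValueError("signal shorter than one 1-s data record")
    n_ch = len(night.channel_names)

    header = b"".join(
        [
            _pad_field("0", 8),
            _pad_field(f"{night.participant_id}", 80),
            _pad_field(f"Startdate 01-JAN-2000 {night.night_id}", 80),
            _pad_field("01.01.00", 8),
            _pad_field("00.00.00", 8),
            _pad_field(str(256 * (1 + n_ch)), 8),
            _pad_field("", 44),
            _pad_field(str(n_rec), 8),
            _pad_field("1", 8),
            _pad_field(str(n_ch), 4),
        ]
    )

    phys_min, phys_max, scaled = [], [], []
    for i in range(n_ch):
        x = night.signal[i, : n_rec * spr]
        lim = max(float(np.max(np.abs(x))), 1.0) * 1.001
        phys_min.append(-lim)
        phys_max.append(lim)
        dig = np.clip(np.round(x / lim * 32767.0), -32768, 32767).astype("<i2")
        scaled.append(dig)

    sig_hdr = b"".join(
        [
            b"".join(_pad_field(name, 16) for name in night.channel_names),
            b"".join(_pad_field("dry electrode", 80) for _ in range(n_ch)),
            b"".join(_pad_field("uV", 8) for _ in range(n_ch)),
            b"".join(_pad_field(f"{phys_min[i]:.3f}"[:8], 8) for i in range(n_ch)),
            b"".join(_pad_field(f"{phys_max[i]:.3f}"[:8], 8) for i in range(n_ch)),
            b"".join(_pad_field("-32768", 8) for _ in range(n_ch)),
            b"".join(_pad_field("32767", 8) for _ in range(n_ch)),
            b"".join(_pad_field("", 80) for _ in range(n_ch)),
            b"".join(_pad_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_pad_field("", 32) for _ in range(n_ch)),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_rec):
            for i in range(n_ch):
                fh.write(scaled[i][r * spr : (r + 1) * spr].tobytes())

    sidecar = path.with_suffix(".quality.json")
    sidecar.write_text(
        json.dumps(
            {
                "participant_id": night.participant_id,
                "night_id": night.night_id,
                "channel_quality": night.channel_quality,
            },
            indent=2,
        )
    )


def read_edf(path: str | Path, channel_quality: dict[str, float] | None = None) -> EEGNight:
    """Read an EDF/EDF+ night into an :class:`EEGNight` (amplitudes in μV).

    Channel quality comes from, in order of precedence: the explicit
    argument, a ``<name>.quality.json`` sidecar, else 1.0 for every channel.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads Volts; internal unit is μV
    names = list(raw.ch_names)

    participant_id, night_id = path.stem, path.stem
    if channel_quality is None:
        sidecar = path.with_suffix(".quality.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            channel_quality = {k: float(v) for k, v in meta["channel_quality"].items()}
            participant_id = meta.get("participant_id", participant_id)
            night_id = meta.get("night_id", night_id)
        else:
            channel_quality = {ch: 1.0 for ch in names}

    return EEGNight(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        channel_quality=channel_quality,
        participant_id=participant_id,
        night_id=night_id,
    )


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(hyp.n_epochs), "stage": hyp.stages}
    ).to_csv(path, index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    df = df.sort_values("epoch_index")
    return Hypnogram(df["stage"].to_numpy(dtype="U4"))


def write_events(path: str | Path, events: list[SleepEvent]) -> None:
    cols = ["type", "onset_s", "duration_s", "channel", "p2p_uV", "env_amp_uV", "stage_at_onset"]
    df = pd.DataFrame([asdict(e) for e in events], columns=cols)
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[SleepEvent]:
    df = pd.read_csv(path)
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SleepEvent(
                type=row.type,
                onset_s=float(row.onset_s),
                duration_s=float(row.duration_s),
                channel="" if pd.isna(row.channel) else str(row.channel),
                p2p_uV=None if pd.isna(row.p2p_uV) else float(row.p2p_uV),
                env_amp_uV=None if pd.isna(row.env_amp_uV) else float(row.env_amp_uV),
                stage_at_onset="" if pd.isna(row.stage_at_onset) else str(row.stage_at_onset),
            )
        )
    return events


def events_to_bed(path: str | Path, events: list[SleepEvent], fs: float, name: str = "night") -> None:
    """Events as 0-based half-open intervals on the sample timeline (BED-like)."""
    with open(path, "w") as fh:
        for e in events:
            a = int(round(e.onset_s * fs))
            b = int(round((e.onset_s + e.duration_s) * fs))
            fh.write(f"{name}\t{a}\t{b}\t{e.type}\n")
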