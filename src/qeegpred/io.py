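"""On-disk interchange: EDF+ recordings and CSV event / feature tables.

Recordings are written as EDF+ (16-bit samples, physical units uV) with the
spike-wave annotations embedded as EDF+ time-stamped annotation lists and
duplicated in a sidecar CSV (``subject_id, onset_s, duration_s, channels``);
the CSV is the authoritative event store for the pipeline.  Reading goes
through :func:`mne.io.read_raw_edf`.

The writer covers exactly what the pipeline produces: continuous
equal-length signals at an integer sampling rate, one-second data records.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEGRecording, SpikeEvent

__all__ = ["write_edf", "read_edf", "write_events_csv", "read_events_csv"]

_EVENT_LABEL = "SpikeWave"


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def _annotation_records(rec: EEGRecording, n_records: int) -> list[bytes]:
    """Per-record EDF+ TAL byte strings (timekeeping + in-record events)."""
    per_record: list[list[SpikeEvent]] = [[] for _ in range(n_records)]
    for ev in rec.events:
        k = min(int(ev.onset), n_records - 1)
        per_record[k].append(ev)
    out = []
    for k in range(n_records):
        tal = f"+{k}\x14\x14\x00"
        for ev in sorted(per_record[k], key=lambda e: e.onset):
            chans = "|".join(ev.channels)
            tal += (f"+{ev.onset:.4f}\x15{ev.duration:.4f}"
                    f"\x14{_EVENT_LABEL}:{chans}\x14\x00")
        out.append(tal.encode("ascii"))
    return out


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as EDF+C (16-bit, physical uV, 1-s data records).

    The final partial second, if any, is zero-padded.  Events are embedded
    as EDF+ annotations (description ``SpikeWave:<ch|ch|...>``).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = max(1, math.ceil(rec.n_samples / fs))
    n_sig = rec.n_channels

    data = np.zeros((n_sig, n_records * fs))
    data[:, : rec.n_samples] = rec.data
    pmax = max(1.0, float(np.abs(data).max()))
    pmax = float(np.ceil(pmax))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * pmax)
    digital = np.round((data + pmax) * scale + dig_min).astype("<i2")

    tals = _annotation_records(rec, n_records)
    ann_bytes = max(len(t) for t in tals) + 2
    ann_samples = (ann_bytes + 1) // 2  # 2 bytes per annotation "sample"

    labels = list(rec.channels) + ["EDF Annotations"]
    header = b""
    header += _ascii_field("0", 8)
    header += _ascii_field(rec.subject_id, 80)
    header += _ascii_field("Startdate 01-JAN-2000 synthetic qeegpred", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (len(labels) + 1), 8)
    header += _ascii_field("EDF+C", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)  # record duration, seconds
    header += _ascii_field(len(labels), 4)

    def sig_fields(values, width):
        return b"".join(_ascii_field(v, width) for v in values)

    header += sig_fields(labels, 16)
    header += sig_fields([""] * len(labels), 80)                       # transducer
    header += sig_fields(["uV"] * n_sig + [""], 8)                     # dimension
    header += sig_fields([-pmax] * n_sig + [-1], 8)                    # physical min
    header += sig_fields([pmax] * n_sig + [1], 8)                      # physical max
    header += sig_fields([dig_min] * n_sig + [-32768], 8)              # digital min
    header += sig_fields([dig_max] * n_sig + [32767], 8)               # digital max
    header += sig_fields([""] * len(labels), 80)                       # prefiltering
    header += sig_fields([fs] * n_sig + [ann_samples], 8)              # samples/record
    header += sig_fields([""] * len(labels), 32)                       # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for k in range(n_records):
            fh.write(digital[:, k * fs:(k + 1) * fs].tobytes())
            tal = tals[k].ljust(2 * ann_samples, b"\x00")
            fh.write(tal)
    return path


def read_edf(path: str | Path, subject_id: str | None = None) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (uV).

    Embedded ``SpikeWave`` annotations are recovered as events; other
    annotations are ignored.
    """
    import mne

    mne.set_log_level("ERROR")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # volts -> uV
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if not desc.startswith(_EVENT_LABEL):
            continue
        chans = tuple(desc.split(":", 1)[1].split("|")) if ":" in desc \
            else tuple(raw.ch_names)
        events.append(SpikeEvent(onset=float(ann["onset"]),
                                 duration=float(ann["duration"]),
                                 channels=chans))
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        events=sorted(events, key=lambda e: e.onset),
        subject_id=subject_id or Path(path).stem,
    )


def write_events_csv(recs: list[EEGRecording] | EEGRecording,
                     path: str | Path) -> Path:
    """Sidecar CSV of all spike-wave events, one row per event."""
    if isinstance(recs, EEGRecording):
        recs = [recs]
    rows = [
        {
            "subject_id": rec.subject_id,
            "onset_s": ev.onset,
            "duration_s": ev.duration,
            "channels": "|".join(ev.channels),
        }
        for rec in recs
        for ev in rec.events
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "onset_s", "duration_s", "channels"])
    df.to_csv(path, index=False)
    return Path(path)


def read_events_csv(path: str | Path) -> dict[str, list[SpikeEvent]]:
    """Events grouped by subject_id."""
    df = pd.read_csv(path)
    out: dict[str, list[SpikeEvent]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            SpikeEvent(
                onset=float(row.onset_s),
                duration=float(row.duration_s),
                channels=tuple(str(row.channels).split("|")),
            )
        )
    return out
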