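"""Core domain objects shared across the pipeline.

The unit of analysis is a 19-channel scalp EEG recorded with the 10-20
placement system, carried through the pipeline as an :class:`EEGRecording`
together with its spike-wave event annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 electrodes of the 10-20 system used for quantitative analysis.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "T5", "T6", "P3", "P4", "O1", "O2",
    "Fz", "Cz", "Pz",
)

N_CHANNELS = len(CHANNELS_1020)
N_PAIRS = N_CHANNELS * (N_CHANNELS - 1) // 2  # 171 unordered electrode pairs

#: Analysis frequency bands (Hz), half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Full analysis range after the 1-40 Hz band-pass; denominator of relative power.
FULL_BAND: tuple[float, float] = (1.0, 40.0)

VALID_FS = (500.0, 1000.0)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low {self.low_hz} >= high {self.high_hz}")


def get_band(band: str | BandDefinition) -> BandDefinition:
    """Resolve a band name ('delta'...'beta') or pass a BandDefinition through."""
    if isinstance(band, BandDefinition):
        return band
    try:
        lo, hi = BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}") from None
    return BandDefinition(band, lo, hi)


@dataclass(frozen=True)
class SpikeEvent:
    """One annotated spike-and-slow-wave complex."""

    onset: float            # seconds from recording start
    duration: float         # seconds
    channels: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")
        if len(self.channels) == 0:
            raise ValueError("event must involve at least one channel")


@dataclass
class EEGRecording:
    """Multichannel EEG signal plus annotations and provenance metadata.

    ``data`` is channels x samples in microvolts.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = CHANNELS_1020
    events: list[SpikeEvent] = field(default_factory=list)
    subject_id: str = "S000"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} channel labels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for ev in self.events:
            if ev.onset + ev.duration > self.duration + 1e-9:
                raise ValueError(f"event at {ev.onset}s extends past end of recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(
            self,
            data=self.data.copy(),
            events=list(self.events),
            meta=dict(self.meta),
        )


def pair_index(channels: tuple[str, ...] = CHANNELS_1020):
    """Upper-triangle (i, j) index arrays in fixed lexicographic pair order."""
    n = len(channels)
    iu = np.triu_indices(n, k=1)
    return iu
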