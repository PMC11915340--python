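"""Spike-wave burden metrics from event annotations.

SWI (spike-wave index) is the percentage of one-second bins of a fixed
NREM window (default the first 300 s) containing any spike-wave activity:
100 x (seconds containing activity) / 300.  SWF (spike-wave frequency) is
the mean number of spike-wave complexes per 100 s of the same window.  Both
operate on annotated events; automatic detection from the waveform is out
of scope (clinically these are read visually).

A subject whose initial SWI is already at or above 50% meets the
electrical-status-epilepticus screening threshold and is excluded from a
prediction cohort (``swi_gate``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import SpikeEvent

__all__ = ["SpikeBurden", "compute_swi", "compute_swf", "swi_gate"]


@dataclass(frozen=True)
class SpikeBurden:
    swi_percent: float
    swf_per_100s: float
    window: tuple[float, float] = (0.0, 300.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.swi_percent <= 100.0:
            raise ValueError("SWI must lie in [0, 100]")
        if self.swf_per_100s < 0:
            raise ValueError("SWF must be >= 0")


def compute_swi(events: Iterable[SpikeEvent],
                window: tuple[float, float] = (0.0, 300.0)) -> float:
    """Percentage of 1-s bins [k, k+1) of the window overlapped by any event.

    A bin counts if the intersection with any event (any channel) has
    positive length; overlapping events never double-count a bin.  Events
    wholly outside the window are ignored.
    """
    start, end = window
    n_bins = int(round(end - start))
    if n_bins <= 0:
        raise ValueError("window must have positive integer length in seconds")
    covered = np.zeros(n_bins, dtype=bool)
    for ev in events:
        lo = max(ev.onset, start)
        hi = min(ev.onset + ev.duration, end)
        if hi <= lo:
            continue
        first = int(np.floor(lo - start))
        last = int(np.ceil(hi - start))  # bins with positive-length overlap
        covered[first:last] = True
    return 100.0 * covered.sum() / n_bins


def compute_swf(events: Iterable[SpikeEvent],
                window: tuple[float, float] = (0.0, 300.0)) -> float:
    """Events whose onset lies in [start, end), per 100 s of window.

    Counts complex onsets (not covered time), so a long event contributes
    once.
    """
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    n = sum(1 for ev in events if start <= ev.onset < end)
    return 100.0 * n / (end - start)


def swi_gate(swi_percent: float, threshold: float = 50.0) -> bool:
    """True if the subject passes screening (SWI below threshold).

    ``swi_percent >= threshold`` fails the gate: the subject already shows
    the sleep-activated discharge pattern and is excluded.
    """
    return swi_percent < threshold


def spike_burden(events: Sequence[SpikeEvent],
                 window: tuple[float, float] = (0.0, 300.0)) -> SpikeBurden:
    return SpikeBurden(
        swi_percent=compute_swi(events, window),
        swf_per_100s=compute_swf(events, window),
        window=window,
    )
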