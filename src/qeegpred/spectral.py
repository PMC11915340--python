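"""Welch power spectral density and band powers (whole-brain averaged).

The PSD is estimated with Welch's method (2-s Hamming windows, 50% overlap)
over the retained epochs of the 5-min segment, giving a 0.5 Hz frequency
grid.  Absolute band power (uV^2) integrates the one-sided density over the
half-open band interval [low, high); relative power divides by the
full-band (1-40 Hz) power, which makes it scale-invariant and hence
comparable across subjects.  Band edges partition: 4 Hz belongs to theta,
8 Hz to alpha, 13 Hz to beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .core import BANDS, FULL_BAND, BandDefinition, get_band
from .preprocess import EpochSet, InsufficientDataError

__all__ = ["PSDResult", "welch_psd", "band_powers"]


@dataclass
class PSDResult:
    """Per-channel PSD plus band-power summaries."""

    freqs: np.ndarray                 # Hz
    psd: np.ndarray                   # channel x frequency, uV^2/Hz
    channels: tuple[str, ...]
    abs_power: dict[str, np.ndarray] = field(default_factory=dict)   # per-channel uV^2
    rel_power: dict[str, np.ndarray] = field(default_factory=dict)   # fractions in [0,1]
    whole_brain_abs: dict[str, float] = field(default_factory=dict)
    whole_brain_rel: dict[str, float] = field(default_factory=dict)
    total_power: np.ndarray | None = None   # per-channel full-band (1-40 Hz) power


def welch_psd(es: EpochSet, window_s: float = 2.0, overlap: float = 0.5) -> PSDResult:
    """Welch PSD of the retained epochs, per channel.

    Epochs are concatenated (they are contiguous by construction) and the
    averaged modified periodogram uses ``window_s`` Hamming windows with
    fractional ``overlap``.  One-sided density in uV^2/Hz on a
    1/window_s Hz grid.
    """
    kept = es.kept()
    if kept.shape[0] == 0:
        raise InsufficientDataError("no retained epochs")
    # epoch x channel x sample -> channel x time
    x = kept.transpose(1, 0, 2).reshape(kept.shape[1], -1)
    nperseg = int(round(window_s * es.fs))
    freqs, psd = scipy.signal.welch(
        x, fs=es.fs, window="hamming", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), detrend=False, axis=-1,
    )
    return PSDResult(freqs=freqs, psd=psd, channels=tuple(es.channels))


def _integrate(freqs: np.ndarray, psd: np.ndarray, low: float, high: float) -> np.ndarray:
    """Integral of the density over [low, high) via the rectangle rule."""
    df = freqs[1] - freqs[0]
    mask = (freqs >= low) & (freqs < high)
    return psd[..., mask].sum(axis=-1) * df


def band_powers(res: PSDResult,
                bands: dict[str, tuple[float, float]] | None = None,
                total_band: tuple[float, float] = FULL_BAND) -> PSDResult:
    """Fill absolute/relative band powers and whole-brain averages in place.

    Relative power is band power divided by the ``total_band`` (default
    1-40 Hz, the filtered range) power.  Zero total power on any channel is
    an error rather than a silent zero.
    """
    bands = bands if bands is not None else BANDS
    total = _integrate(res.freqs, res.psd, *total_band)
    if np.any(total <= 0):
        raise ValueError("zero full-band power: relative power undefined")
    res.total_power = total
    for name, (lo, hi) in bands.items():
        get_band(BandDefinition(name, lo, hi))  # validates low < high
        p = _integrate(res.freqs, res.psd, lo, hi)
        res.abs_power[name] = p
        res.rel_power[name] = p / total
        res.whole_brain_abs[name] = float(p.mean())
        res.whole_brain_rel[name] = float((p / total).mean())
    return res
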