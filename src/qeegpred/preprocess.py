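"""Raw recording -> analysis-ready epoch sets.

The analysis chain mirrors standard clinical qEEG practice: zero-phase
band-pass 1-40 Hz, resample to 500 Hz, cut the first 5 minutes of the
(annotated) NREM segment into contiguous 2-s epochs, amplitude-threshold
artifact flagging, common-average re-referencing, and - for connectivity
only - a spherical-spline current-source-density (surface Laplacian)
transform that removes reference and volume-conduction common sources.

Filters are linear-phase FIR (Hamming window, transition width 25% of the
band edge) applied once with group-delay compensation, so the pass band is
exactly zero-phase: phase distortion would corrupt the phase-synchrony
metrics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.fft
import scipy.signal

from .core import CHANNELS_1020, EEGRecording

__all__ = [
    "EpochSet",
    "bandpass_filter",
    "resample",
    "make_epochs",
    "reject_artifacts",
    "common_average_reference",
    "csd_transform",
    "fir_bandpass",
    "preprocess_recording",
]


class InsufficientDataError(ValueError):
    """Recording shorter than the requested analysis segment."""


@dataclass
class EpochSet:
    """Fixed-length contiguous epochs (epoch x channel x sample)."""

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    channels: tuple[str, ...] = CHANNELS_1020
    reference: str = "raw"          # raw | common_average | csd
    kept_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch has {self.epochs.shape[2]} samples, expected {expected}"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != (self.epochs.shape[0],):
            raise ValueError("kept_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def kept(self) -> np.ndarray:
        """Data of retained epochs only."""
        return self.epochs[self.kept_mask]

    def copy(self) -> "EpochSet":
        return replace(self, epochs=self.epochs.copy(), kept_mask=self.kept_mask.copy())


def fir_bandpass(low_hz: float, high_hz: float, fs: float,
                 max_taps: int | None = None) -> np.ndarray:
    """Hamming-window FIR band-pass, transition width 25% of each edge.

    Tap count is set by the narrower (lower) transition band; an odd length
    (type-I linear phase) is enforced so the group delay is an integer.
    """
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) for fs={fs}")
    trans = 0.25 * low_hz
    # Hamming main-lobe transition width ~= 3.3 / N (in units of fs)
    n_taps = int(math.ceil(3.3 * fs / trans))
    if max_taps is not None:
        n_taps = min(n_taps, max_taps)
    n_taps |= 1
    return scipy.signal.firwin(
        n_taps, [low_hz, high_hz], pass_zero=False, window="hamming", fs=fs
    )


def _filter_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with delay compensation (zero net phase).

    The signal is reflection-padded and multiplied in the frequency domain
    by the filter's delay-compensated (real) response, which is identical to
    convolving with the FIR and shifting by its group delay but costs one
    FFT round trip instead of a long convolution.
    """
    delay = (len(taps) - 1) // 2
    pad = min(delay, data.shape[-1] - 1)
    padded = np.concatenate(
        [data[..., pad:0:-1], data, data[..., -2:-pad - 2:-1]], axis=-1
    )
    n_fft = scipy.fft.next_fast_len(padded.shape[-1])
    freqs = np.fft.rfftfreq(n_fft)
    # symmetric taps: H(f) e^{+i 2 pi f delay} is purely real
    h = np.real(scipy.fft.rfft(taps, n_fft) * np.exp(2j * np.pi * freqs * delay))
    out = scipy.fft.irfft(scipy.fft.rfft(padded, n_fft, axis=-1) * h,
                          n=n_fft, axis=-1)
    return out[..., pad:pad + data.shape[-1]]


def bandpass_filter(rec: EEGRecording, low_hz: float = 1.0,
                    high_hz: float = 40.0) -> EEGRecording:
    """Zero-phase 1-40 Hz band-pass of a recording."""
    taps = fir_bandpass(low_hz, high_hz, rec.fs, max_taps=rec.n_samples)
    out = rec.copy()
    out.data = _filter_zero_phase(rec.data, taps)
    out.meta["bandpass_hz"] = (low_hz, high_hz)
    return out


def resample(rec: EEGRecording, target_fs: float = 500.0) -> EEGRecording:
    """Downsample (polyphase, anti-aliased) to target_fs; identity if equal."""
    if target_fs > rec.fs:
        raise ValueError("upsampling is out of scope (target_fs > fs)")
    if target_fs == rec.fs:
        return rec.copy()
    up = int(target_fs)
    down = int(rec.fs)
    g = math.gcd(up, down)
    data = scipy.signal.resample_poly(rec.data, up // g, down // g, axis=-1)
    out = rec.copy()
    out.data = data
    out.fs = target_fs
    return out


def make_epochs(rec: EEGRecording, epoch_length_s: float = 2.0,
                total_s: float = 300.0, start_s: float = 0.0) -> EpochSet:
    """Cut [start_s, start_s+total_s) into contiguous non-overlapping epochs.

    Windows are half-open [t, t+epoch_length_s) with 0-based sample indexing;
    concatenating the epochs reproduces the segment exactly.
    """
    n_per = int(round(epoch_length_s * rec.fs))
    n_ep = int(round(total_s / epoch_length_s))
    start = int(round(start_s * rec.fs))
    need = start + n_ep * n_per
    if need > rec.n_samples:
        raise InsufficientDataError(
            f"recording has {rec.n_samples / rec.fs:.1f} s, "
            f"needs {need / rec.fs:.1f} s"
        )
    seg = rec.data[:, start:need]
    epochs = seg.reshape(rec.n_channels, n_ep, n_per).transpose(1, 0, 2).copy()
    return EpochSet(
        epochs=epochs, fs=rec.fs, epoch_length_s=epoch_length_s,
        channels=tuple(rec.channels),
    )


def reject_artifacts(es: EpochSet, peak_uv: float = 200.0) -> EpochSet:
    """Flag epochs whose absolute amplitude exceeds peak_uv on any channel.

    Automated stand-in for manual artifact review: data is unchanged, only
    ``kept_mask`` is updated (AND-ed with any existing mask).
    """
    if es.reference == "csd":
        raise ValueError("amplitude rejection expects raw/common-average units (uV)")
    ok = np.abs(es.epochs).max(axis=(1, 2)) <= peak_uv
    out = es.copy()
    out.kept_mask = es.kept_mask & ok
    return out


def common_average_reference(es: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels from every sample."""
    if es.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    out = es.copy()
    out.epochs = es.epochs - es.epochs.mean(axis=1, keepdims=True)
    out.reference = "common_average"
    return out


_MONTAGE_CACHE: dict = {}


def _mne_info(channels: tuple[str, ...], fs: float):
    import mne

    key = (channels, fs)
    if key not in _MONTAGE_CACHE:
        mne.set_log_level("ERROR")
        info = mne.create_info(list(channels), fs, ch_types="eeg")
        montage = mne.channels.make_standard_montage("standard_1020")
        info.set_montage(montage)
        _MONTAGE_CACHE[key] = info
    return _MONTAGE_CACHE[key]


def csd_operator(channels: tuple[str, ...], fs: float = 500.0,
                 stiffness: int = 4, lambda2: float = 1e-5,
                 n_legendre_terms: int = 50) -> np.ndarray:
    """Per-sample CSD matrix M such that csd_data[:, t] = M @ data[:, t].

    The spherical-spline transform is linear and instantaneous, so it is
    extracted once (by transforming an identity 'epoch') and cached; this
    keeps per-recording cost to a single matrix product.
    """
    key = (channels, stiffness, lambda2, n_legendre_terms, "op")
    if key not in _MONTAGE_CACHE:
        import mne

        info = _mne_info(channels, fs)
        eye = np.eye(len(channels))[None, :, :]
        epo = mne.EpochsArray(eye, info, verbose="ERROR")
        csd = mne.preprocessing.compute_current_source_density(
            epo, stiffness=stiffness, lambda2=lambda2,
            n_legendre_terms=n_legendre_terms, copy=True, verbose="ERROR",
        )
        _MONTAGE_CACHE[key] = csd.get_data(copy=True)[0]
    return _MONTAGE_CACHE[key]


def csd_transform(es: EpochSet, stiffness: int = 4, lambda2: float = 1e-5,
                  n_legendre_terms: int = 50) -> EpochSet:
    """Spherical-spline surface Laplacian (current source density).

    Electrode positions come from the standard 10-20 montage.  The output is
    reference-free: adding a spatially uniform offset to the input leaves it
    unchanged.  Units become uV/m^2 (scalp current density); downstream
    phase metrics are amplitude-invariant so the unit change is immaterial.
    """
    m = csd_operator(tuple(es.channels), es.fs, stiffness, lambda2,
                     n_legendre_terms)
    out = es.copy()
    out.epochs = np.einsum("cd,edt->ect", m, es.epochs)
    out.reference = "csd"
    return out


def preprocess_recording(
    rec: EEGRecording,
    low_hz: float = 1.0,
    high_hz: float = 40.0,
    target_fs: float = 500.0,
    epoch_length_s: float = 2.0,
    total_s: float | None = None,
    reject_peak_uv: float = 200.0,
    csd: bool = False,
) -> EpochSet:
    """Full default chain: filter -> resample -> epoch -> reject -> CAR [-> CSD].

    ``total_s`` defaults to the full recording length rounded down to a whole
    number of epochs, capped at 300 s (the 5-min analysis segment).
    """
    rec = bandpass_filter(rec, low_hz, high_hz)
    rec = resample(rec, target_fs)
    if total_s is None:
        total_s = min(300.0, math.floor(rec.duration / epoch_length_s) * epoch_length_s)
    es = make_epochs(rec, epoch_length_s, total_s)
    es = reject_artifacts(es, reject_peak_uv)
    es = common_average_reference(es)
    if csd:
        es = csd_transform(es)
    return es
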