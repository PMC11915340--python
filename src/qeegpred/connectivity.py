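"""Phase-synchrony functional connectivity (PLV, PLI, wPLI).

Signals are current-source-density transformed, band-pass filtered to the
target band, and Hilbert-transformed to analytic form.  Metrics are
computed within each 2-s epoch over the central 80% of samples (Hilbert
edge effects) and then averaged across epochs:

* PLV  = |<exp(i dphi)>|            - consistency of the phase difference;
  inflated by zero-lag (volume-conducted) mixing.
* PLI  = |<sign(sin dphi)>|         - asymmetry of the phase-difference
  sign; blind to zero-lag coupling (sign(0) counts as 0).
* wPLI = |<Im S>| / <|Im S|>        - imaginary cross-spectrum weighted;
  robust to zero-lag mixing and noise.

A tapered-FFT PLV variant (single Hann taper, 1 Hz frequency resolution,
phase consistency *across epochs* per frequency bin) supplies the edge
weights for graph construction.

The global value of a metric in a band is its mean over all 171 unordered
electrode pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.signal

from .core import BandDefinition, get_band, pair_index
from .preprocess import EpochSet, InsufficientDataError, _filter_zero_phase, fir_bandpass

__all__ = [
    "ConnMatrix",
    "GlobalCoupling",
    "band_filter_epochs",
    "instantaneous_phase",
    "analytic_epochs",
    "plv",
    "pli",
    "wpli",
    "connectivity_matrix",
    "connectivity_matrices",
    "plv_fft",
    "global_value",
]


@dataclass
class ConnMatrix:
    metric: str                      # PLV | PLI | wPLI | PLV_fft
    band: BandDefinition
    values: np.ndarray               # n_channels x n_channels, symmetric
    n_epochs: int
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v


@dataclass(frozen=True)
class GlobalCoupling:
    metric: str
    band: str
    value: float
    n_pairs: int


def band_filter_epochs(es: EpochSet, band) -> EpochSet:
    """Zero-phase band-pass of an epoch set in its target band.

    Epochs are contiguous by construction, so the concatenated segment is
    filtered as one continuous signal and re-split; this avoids per-epoch
    filter transients for low-frequency bands.
    """
    bd = get_band(band)
    if bd.high_hz >= es.fs / 2:
        raise ValueError(f"band {bd.name} exceeds Nyquist for fs={es.fs}")
    n_ep, n_ch, n_s = es.epochs.shape
    cont = es.epochs.transpose(1, 0, 2).reshape(n_ch, n_ep * n_s)
    taps = fir_bandpass(bd.low_hz, bd.high_hz, es.fs, max_taps=cont.shape[-1])
    filt = _filter_zero_phase(cont, taps)
    out = es.copy()
    out.epochs = filt.reshape(n_ch, n_ep, n_s).transpose(1, 0, 2)
    return out


def analytic_epochs(es: EpochSet, band) -> np.ndarray:
    """Band-filter then per-epoch Hilbert analytic signal of kept epochs."""
    filt = band_filter_epochs(es, band)
    return scipy.signal.hilbert(filt.kept(), axis=-1)


class _AnalyticCache:
    """Band-filtered analytic signals of one epoch set, sharing one FFT.

    The concatenated segment is Fourier-transformed once; each band's
    zero-phase FIR response is applied in the frequency domain and the
    analytic signal obtained by zeroing negative frequencies (Hilbert), so
    computing several bands costs one inverse FFT each.  Numerically
    equivalent to ``analytic_epochs`` up to the per-epoch vs continuous
    Hilbert edge treatment, which the central-sample trim absorbs.
    """

    def __init__(self, es: EpochSet):
        self.es = es
        n_ep, n_ch, n_s = es.epochs.shape
        self._shape = (n_ch, n_ep, n_s)
        cont = es.epochs.transpose(1, 0, 2).reshape(n_ch, n_ep * n_s)
        delay_probe = fir_bandpass(1.0, min(40.0, es.fs / 2 - 1), es.fs,
                                   max_taps=cont.shape[-1])
        self._pad = min((len(delay_probe) - 1) // 2, cont.shape[-1] - 1)
        pad = self._pad
        padded = np.concatenate(
            [cont[..., pad:0:-1], cont, cont[..., -2:-pad - 2:-1]], axis=-1
        )
        self._padded_n = scipy.fft.next_fast_len(padded.shape[-1])
        self._spec = scipy.fft.fft(padded, self._padded_n, axis=-1)
        self._freqs = np.fft.fftfreq(self._padded_n, 1.0 / es.fs)

    def analytic(self, band) -> np.ndarray:
        bd = get_band(band)
        if bd.high_hz >= self.es.fs / 2:
            raise ValueError(f"band {bd.name} exceeds Nyquist for fs={self.es.fs}")
        taps = fir_bandpass(bd.low_hz, bd.high_hz, self.es.fs,
                            max_taps=self._shape[1] * self._shape[2])
        delay = (len(taps) - 1) // 2
        h = np.real(
            scipy.fft.fft(taps, self._padded_n)
            * np.exp(2j * np.pi * np.fft.fftfreq(self._padded_n) * delay)
        )
        # analytic signal: double positive frequencies, zero negative ones
        gain = np.where(self._freqs > 0, 2.0, 0.0)
        gain[self._freqs == 0] = 1.0
        z = scipy.fft.ifft(self._spec * (h * gain), axis=-1)
        pad = self._pad
        n_ch, n_ep, n_s = self._shape
        z = z[..., pad:pad + n_ep * n_s]
        return z.reshape(n_ch, n_ep, n_s).transpose(1, 0, 2)[self.es.kept_mask]


def instantaneous_phase(es: EpochSet, band) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) per kept epoch and channel.

    The first and last 10% of each epoch carry Hilbert edge distortion;
    downstream metrics exclude them via ``central_slice``.
    """
    return np.angle(analytic_epochs(es, band))


def central_slice(n_samples: int, edge_fraction: float = 0.1) -> slice:
    """Sample slice excluding edge_fraction of samples at each end."""
    k = int(round(edge_fraction * n_samples))
    return slice(k, n_samples - k)


def _epoch_mean(per_epoch: np.ndarray) -> float:
    """Average a per-epoch metric, propagating all-NaN as NaN with a warning."""
    if np.all(np.isnan(per_epoch)):
        return float("nan")
    if np.any(np.isnan(per_epoch)):
        warnings.warn("undefined metric in some epochs; averaged over the rest")
    return float(np.nanmean(per_epoch))


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-locking value, per epoch over the last axis, averaged across epochs."""
    a, b = np.asarray(phase_a), np.asarray(phase_b)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal shapes")
    per = np.abs(np.exp(1j * (a - b)).mean(axis=-1))
    return float(np.mean(per))


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase lag index; sign(0) counts as 0, so zero-lag signals give 0."""
    a, b = np.asarray(phase_a), np.asarray(phase_b)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal shapes")
    per = np.abs(np.sign(np.sin(a - b)).mean(axis=-1))
    return float(np.mean(per))


def wpli(analytic_a: np.ndarray, analytic_b: np.ndarray) -> float:
    """Weighted phase lag index from analytic signals.

    Uses the per-sample cross-spectrum S = z_a * conj(z_b): per epoch
    |<Im S>| / <|Im S|>, averaged across epochs.  All-zero imaginary parts
    make the epoch undefined (NaN), not 0.
    """
    za, zb = np.asarray(analytic_a), np.asarray(analytic_b)
    if za.shape != zb.shape:
        raise ValueError("analytic series must have equal shapes")
    im = np.imag(za * np.conj(zb))
    num = np.abs(im.mean(axis=-1))
    den = np.abs(im).mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per = np.where(den > 0, num / den, np.nan)
    return _epoch_mean(np.atleast_1d(per))


_METRIC_NAMES = {"PLV": "PLV", "PLI": "PLI", "WPLI": "wPLI"}


def connectivity_matrices(es: EpochSet, band,
                          metrics: tuple[str, ...] = ("PLV", "PLI", "wPLI"),
                          edge_fraction: float = 0.1,
                          cache: "_AnalyticCache | None" = None
                          ) -> dict[str, ConnMatrix]:
    """All requested pairwise matrices for one band in a single pass.

    Per-epoch values over the central samples, averaged across kept epochs.
    Sharing the band-filtered analytic signal across metrics (and, via
    ``cache``, the raw-signal FFT across bands) avoids redundant filtering.
    """
    names = []
    for m in metrics:
        try:
            names.append(_METRIC_NAMES[m.upper()])
        except KeyError:
            raise ValueError(f"unknown metric {m!r}") from None
    bd = get_band(band)
    if cache is None:
        cache = _AnalyticCache(es)
    z = cache.analytic(bd)
    if z.shape[0] == 0:
        raise InsufficientDataError("no retained epochs")
    z = z[..., central_slice(z.shape[-1], edge_fraction)]
    # single precision is ample for sample means of unit-scale quantities
    z = np.ascontiguousarray(z, dtype=np.complex64)
    n_ep, n_ch, _ = z.shape
    iu_i, iu_j = np.triu_indices(n_ch, k=1)
    # epochs x pairs x samples cross-spectrum, all pairs at once
    d = z[:, iu_i, :] * np.conj(z[:, iu_j, :])
    vals: dict[str, np.ndarray] = {}
    if "PLV" in names:
        mag = np.abs(d)
        mag[mag == 0] = 1.0
        vals["PLV"] = np.abs((d / mag).mean(axis=-1)).mean(axis=0)
    if "PLI" in names:
        vals["PLI"] = np.abs(np.sign(d.imag).mean(axis=-1)).mean(axis=0)
    if "wPLI" in names:
        num = np.abs(d.imag.mean(axis=-1))
        den = np.abs(d.imag).mean(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per = np.where(den > 0, num / den, np.nan)   # epochs x pairs
        all_nan = np.all(np.isnan(per), axis=0)
        if np.any(np.isnan(per) & ~all_nan[None, :]):
            warnings.warn("undefined wPLI in some epochs; averaged over the rest")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals["wPLI"] = np.nanmean(per, axis=0)
    out = {}
    for m in names:
        mat = np.zeros((n_ch, n_ch))
        mat[iu_i, iu_j] = vals[m]
        mat = mat + mat.T
        out[m] = ConnMatrix(metric=m, band=bd, values=mat,
                            n_epochs=n_ep, channels=tuple(es.channels))
    return out


def connectivity_matrix(es: EpochSet, metric: str, band,
                        edge_fraction: float = 0.1) -> ConnMatrix:
    """Full 19x19 pairwise matrix of PLV, PLI or wPLI in one band."""
    name = _METRIC_NAMES.get(metric.upper())
    if name is None:
        raise ValueError(f"unknown metric {metric!r}")
    return connectivity_matrices(es, band, (name,), edge_fraction)[name]


#: Public alias: reusable across-band analytic-signal cache for one epoch set.
AnalyticCache = _AnalyticCache


def plv_fft(es: EpochSet, band, freq_resolution: float = 1.0,
            edge_fraction: float = 0.0) -> ConnMatrix:
    """Across-epoch PLV from single-Hann-taper FFT spectra (graph edges).

    Each 2-s epoch is tapered and Fourier-transformed (0.5 Hz native grid);
    bins are decimated to the ``freq_resolution`` grid.  Per bin the PLV is
    the modulus of the across-epoch mean of the unit-normalised cross
    spectrum; the band value averages the bins with low <= f < high.
    """
    bd = get_band(band)
    if bd.high_hz >= es.fs / 2:
        raise ValueError(f"band {bd.name} exceeds Nyquist for fs={es.fs}")
    x = es.kept()
    if x.shape[0] == 0:
        raise InsufficientDataError("no retained epochs")
    n_ep, n_ch, n_s = x.shape
    taper = scipy.signal.windows.hann(n_s, sym=False)
    spec = np.fft.rfft(x * taper, axis=-1)
    freqs = np.fft.rfftfreq(n_s, 1.0 / es.fs)
    on_grid = np.isclose(freqs / freq_resolution, np.round(freqs / freq_resolution),
                         atol=1e-9)
    in_band = (freqs >= bd.low_hz) & (freqs < bd.high_hz) & on_grid
    if not in_band.any():
        raise ValueError(
            f"band {bd.name} contains no bins at {freq_resolution} Hz resolution"
        )
    u = spec[:, :, in_band]
    mag = np.abs(u)
    mag[mag == 0] = 1.0
    u = u / mag
    # PLV across epochs per bin: |mean_e u_a conj(u_b)|
    vals = np.zeros((n_ch, n_ch))
    for b in range(u.shape[-1]):
        ub = u[:, :, b]
        m = ub.T @ np.conj(ub) / n_ep
        vals += np.abs(m)
    vals /= u.shape[-1]
    np.fill_diagonal(vals, 0.0)
    vals = 0.5 * (vals + vals.T)
    return ConnMatrix(metric="PLV_fft", band=bd, values=vals,
                      n_epochs=n_ep, channels=tuple(es.channels))


def global_value(cm: ConnMatrix) -> GlobalCoupling:
    """Mean over the 171 unordered electrode pairs (upper triangle).

    Missing (NaN) pairs are excluded with a warning; the count of pairs
    actually averaged is reported.
    """
    iu = pair_index(tuple(range(cm.values.shape[0])))
    vals = cm.values[iu]
    finite = np.isfinite(vals)
    if not finite.all():
        warnings.warn(f"{(~finite).sum()} pair(s) missing; global over the rest")
    if not finite.any():
        return GlobalCoupling(cm.metric, cm.band.name, float("nan"), 0)
    return GlobalCoupling(cm.metric, cm.band.name,
                          float(vals[finite].mean()), int(finite.sum()))
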