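"""Complex signal representations: STFT coefficients and analytic signals.

Two routes from a real multichannel recording to the complex samples the
higher-order statistics consume:

* frequency domain — short-time Fourier transform with 1-s Hann windows and
  50% overlap; the coefficient sequence at one frequency bin per channel;
* time domain — zero-phase 4th-order Butterworth band-pass (center +/- 2 Hz),
  Hilbert analytic signal, decimation by 5.

Both produce (channels x samples) complex arrays whose rows are the inputs to
:mod:`cokurt.hos`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesSet",
    "TFCoefficients",
    "stft_at_frequency",
    "analytic_band",
    "group_peak_frequency",
]


@dataclass
class TimeSeriesSet:
    """Real multichannel recording: (channels x samples) at sampling rate fs."""

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("NaNs in time series")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TFCoefficients:
    """Complex coefficients (channels x windows/samples) at one frequency."""

    coeffs: np.ndarray
    frequency: float
    fs: float
    labels: list[str] = field(default_factory=list)
    window_s: float | None = None
    overlap: float | None = None


def stft_at_frequency(
    ts: TimeSeriesSet,
    freq: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> TFCoefficients:
    """STFT coefficient sequence at the bin nearest ``freq``.

    Hann taper, window length ``window_s`` seconds, fractional ``overlap``
    (0.5 by default, giving 1-Hz bin spacing for 1-s windows at integer fs).
    """
    nper = int(round(window_s * ts.fs))
    if ts.n_samples < nper:
        raise ValueError("signal shorter than one STFT window")
    if freq > ts.fs / 2:
        raise ValueError("requested frequency above Nyquist")
    noverlap = int(round(nper * overlap))
    f, _, Z = sps.stft(
        ts.data,
        fs=ts.fs,
        window="hann",
        nperseg=nper,
        noverlap=noverlap,
        boundary=None,
        padded=False,
    )
    bin_idx = int(np.argmin(np.abs(f - freq)))
    coeffs = Z[:, bin_idx, :]
    return TFCoefficients(
        coeffs=np.asarray(coeffs, dtype=complex),
        frequency=float(f[bin_idx]),
        fs=ts.fs / (nper - noverlap),
        labels=list(ts.labels),
        window_s=window_s,
        overlap=overlap,
    )


def analytic_band(
    ts: TimeSeriesSet,
    center: float,
    half_bandwidth: float = 2.0,
    order: int = 4,
    decimate_by: int = 5,
) -> TFCoefficients:
    """Band-limited analytic signal around ``center`` Hz.

    Zero-phase (forward-backward) Butterworth band-pass of the given order in
    [center-half_bandwidth, center+half_bandwidth], Hilbert transform, then
    decimation.  The band-pass already acts as the anti-alias filter provided
    the decimated Nyquist stays above the upper band edge; an explicit
    low-pass is added otherwise.
    """
    lo = center - half_bandwidth
    hi = center + half_bandwidth
    nyq = ts.fs / 2
    if lo <= 0 or hi >= nyq:
        raise ValueError(f"band [{lo}, {hi}] Hz outside (0, Nyquist={nyq}) Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, ts.data, axis=-1)
    analytic = sps.hilbert(filtered, axis=-1)
    if decimate_by > 1:
        new_nyq = ts.fs / (2 * decimate_by)
        if hi >= new_nyq:
            # band-limitation alone no longer prevents aliasing
            filtered = sps.decimate(filtered, decimate_by, ftype="fir", axis=-1)
            analytic = sps.hilbert(filtered, axis=-1)
        else:
            analytic = analytic[:, ::decimate_by]
    return TFCoefficients(
        coeffs=np.asarray(analytic, dtype=complex),
        frequency=float(center),
        fs=ts.fs / decimate_by,
        labels=list(ts.labels),
    )


def group_peak_frequency(
    spectra: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float],
) -> float:
    """Frequency of maximum subject-averaged power within ``band``.

    ``spectra`` is (subjects x frequencies) power; ties and flat spectra
    resolve to the lowest tied frequency (logged).  A band with no local
    structure (all-equal power) falls back to the band center with a warning.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("band contains no frequency samples")
    mean_power = spectra.mean(axis=0)[mask]
    band_freqs = freqs[mask]
    if np.ptp(mean_power) == 0.0:
        center = 0.5 * (lo + hi)
        logger.warning("flat spectrum in band %s; falling back to band center %g Hz", band, center)
        return float(band_freqs[np.argmin(np.abs(band_freqs - center))])
    peaks = np.flatnonzero(mean_power == mean_power.max())
    if peaks.size > 1:
        logger.info("tied spectral peaks at %s Hz; choosing lowest", band_freqs[peaks])
    return float(band_freqs[peaks[0]])


def welch_spectra(ts: TimeSeriesSet, window_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel Welch power spectra (helper for peak-frequency selection)."""
    nper = int(round(window_s * ts.fs))
    f, p = sps.welch(ts.data, fs=ts.fs, nperseg=min(nper, ts.n_samples))
    return f, p
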