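"""Per-epoch multitaper spectral features from raw single-channel EEG.

The feature pipeline mirrors standard sleep-EEG practice: the raw trace is
bandpass filtered between 0.1 and 50 Hz with a zero-phase forward–backward
Butterworth filter, cut into 30-s epochs, and each epoch is reduced to log
band powers integrated from a multitaper power-spectral-density estimate
(discrete prolate spheroidal tapers, time-bandwidth 4, 7 tapers by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.signal.windows import dpss

from .exceptions import FormatError, ValidationError

#: Default integration bands in Hz: delta, theta, alpha, sigma, beta, gamma-ish.
DEFAULT_BAND_EDGES: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 16.0),
    (16.0, 30.0),
    (30.0, 50.0),
)

#: Power floor applied before the log so silent epochs stay finite.
POWER_FLOOR = 1e-12


@dataclass
class SpectralFeatures:
    """T×F per-epoch log band powers (dB-like, ``10·log10``).

    ``freq_bins`` holds the F band-center frequencies in Hz and
    ``band_edges`` the half-open integration intervals they summarise.
    """

    matrix: np.ndarray
    freq_bins: np.ndarray
    band_edges: tuple[tuple[float, float], ...]
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.freq_bins = np.asarray(self.freq_bins, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("feature matrix must be 2-D (epochs x bands)")
        if not np.isfinite(self.matrix).all():
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def _columns(self) -> list[str]:
        return [f"power_{low:g}_{high:g}Hz" for low, high in self.band_edges]

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.matrix, columns=self._columns())
        frame.insert(0, "epoch_index", np.arange(self.n_epochs))
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, epoch_seconds: float = 30.0) -> "SpectralFeatures":
        frame = pd.read_csv(path)
        if "epoch_index" not in frame.columns:
            raise FormatError(f"features CSV {path} is missing column 'epoch_index'")
        power_cols = [c for c in frame.columns if c.startswith("power_")]
        if not power_cols:
            raise FormatError(f"features CSV {path} has no power_* columns")
        edges = []
        for name in power_cols:
            low, high = name[len("power_") : -len("Hz")].split("_")
            edges.append((float(low), float(high)))
        matrix = frame.sort_values("epoch_index")[power_cols].to_numpy(dtype=float)
        centers = np.array([(lo + hi) / 2 for lo, hi in edges])
        return cls(matrix=matrix, freq_bins=centers, band_edges=tuple(edges), epoch_seconds=epoch_seconds)


def bandpass_zero_phase(
    signal: np.ndarray,
    low_hz: float = 0.1,
    high_hz: float = 50.0,
    sample_rate_hz: float = 250.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase forward–backward Butterworth bandpass.

    The filter is applied forward then backward (``sosfiltfilt``), so the net
    phase shift is zero and the effective magnitude response is squared.

    Raises
    ------
    ValidationError
        If the cutoffs are not ``0 < low < high < Nyquist``.
    """
    signal = np.asarray(signal, dtype=float)
    nyquist = sample_rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValidationError(f"require 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValidationError(f"high cutoff {high_hz} Hz >= Nyquist {nyquist} Hz")
    if signal.size == 0:
        return signal.copy()
    sos = sps.butter(order, (low_hz, high_hz), btype="bandpass", output="sos", fs=sample_rate_hz)
    return sps.sosfiltfilt(sos, signal)


def _validate_tapers(time_bandwidth: float, n_tapers: int) -> None:
    if n_tapers < 1:
        raise ValidationError("n_tapers must be >= 1")
    if time_bandwidth <= 0:
        raise ValidationError("time_bandwidth must be positive")
    max_tapers = int(np.floor(2 * time_bandwidth)) - 1
    if n_tapers > max_tapers:
        raise ValidationError(
            f"n_tapers={n_tapers} inconsistent with time_bandwidth={time_bandwidth} "
            f"(at most {max_tapers} well-concentrated tapers exist)"
        )


def multitaper_psd(
    epochs: np.ndarray,
    sample_rate_hz: float,
    time_bandwidth: float = 4.0,
    n_tapers: int = 7,
    chunk: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper one-sided PSD of each row of ``epochs``.

    Returns ``(freqs, psd)`` with ``psd`` of shape ``(T, len(freqs))`` in
    power per Hz, so that ``psd.sum(axis=1) * df`` recovers each epoch's
    variance (Parseval).  Tapers are unit-energy DPSS sequences averaged with
    equal weights.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    _validate_tapers(time_bandwidth, n_tapers)
    n_samples = epochs.shape[1]
    tapers = dpss(n_samples, time_bandwidth, Kmax=n_tapers)  # (K, L), unit energy
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate_hz)
    psd = np.empty((epochs.shape[0], freqs.size), dtype=float)
    for start in range(0, epochs.shape[0], chunk):
        block = epochs[start : start + chunk]
        spectra = np.fft.rfft(block[:, None, :] * tapers[None, :, :], axis=-1)
        power = (np.abs(spectra) ** 2).mean(axis=1) / sample_rate_hz
        # one-sided: double everything except DC (and Nyquist when present)
        power[:, 1:] *= 2.0
        if n_samples % 2 == 0:
            power[:, -1] /= 2.0
        psd[start : start + chunk] = power
    return freqs, psd


def multitaper_epoch_features(
    signal: np.ndarray,
    sample_rate_hz: float,
    epoch_seconds: float = 30.0,
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BAND_EDGES,
    time_bandwidth: float = 4.0,
    n_tapers: int = 7,
) -> SpectralFeatures:
    """Log band-power features, one row per 30-s epoch.

    The signal is split into half-open sample windows ``[k·L, (k+1)·L)``; a
    trailing partial epoch is dropped with a warning.  Band power is the PSD
    integrated over each ``[low, high)`` interval, floored at
    :data:`POWER_FLOOR`, then expressed as ``10·log10``.
    """
    signal = np.asarray(signal, dtype=float)
    epoch_len = int(round(epoch_seconds * sample_rate_hz))
    if epoch_len < 2:
        raise ValidationError("epoch too short for spectral estimation")
    _validate_tapers(time_bandwidth, n_tapers)
    n_epochs = signal.size // epoch_len
    if signal.size % epoch_len:
        warnings.warn(
            f"dropping trailing partial epoch of {signal.size % epoch_len} samples",
            stacklevel=2,
        )
    centers = np.array([(low + high) / 2 for low, high in band_edges])
    if n_epochs == 0:
        return SpectralFeatures(
            matrix=np.empty((0, len(band_edges))),
            freq_bins=centers,
            band_edges=tuple(band_edges),
            epoch_seconds=epoch_seconds,
        )
    epochs = signal[: n_epochs * epoch_len].reshape(n_epochs, epoch_len)
    freqs, psd = multitaper_psd(epochs, sample_rate_hz, time_bandwidth, n_tapers)
    df = freqs[1] - freqs[0]
    matrix = np.empty((n_epochs, len(band_edges)), dtype=float)
    for j, (low, high) in enumerate(band_edges):
        mask = (freqs >= low) & (freqs < high)
        if not mask.any():
            raise ValidationError(f"band ({low}, {high}) Hz contains no frequency bins")
        matrix[:, j] = psd[:, mask].sum(axis=1) * df
    matrix = 10.0 * np.log10(np.maximum(matrix, POWER_FLOOR))
    return SpectralFeatures(
        matrix=matrix,
        freq_bins=centers,
        band_edges=tuple(band_edges),
        epoch_seconds=epoch_seconds,
    )
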