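"""Welch power spectral density estimation from overlapping epochs.

Continuous region-level recordings are segmented into fixed-length,
heavily overlapping epochs; each epoch is mean-removed, Hamming-tapered
and Fourier transformed, and the one-sided periodograms are averaged.
With 5-s epochs and no zero-padding the frequency grid has an exact
spacing of 0.2 Hz, which sets the native resolution of every downstream
peak estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

__all__ = [
    "Recording",
    "SpectralConfig",
    "PowerSpectrum",
    "segment_into_epochs",
    "enforce_minimum_epochs",
    "welch_psd",
    "recording_psd",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Epoching and tapering parameters for Welch PSD estimation.

    Attributes
    ----------
    epoch_seconds : float
        Epoch length in seconds (default 5 s, giving 0.2 Hz resolution).
    overlap_fraction : float
        Fractional overlap between consecutive epochs, in [0, 1).
    window : str
        Taper name understood by :func:`scipy.signal.get_window`.
    min_epochs : int
        Minimum number of epochs for a recording to enter analysis
        (10 epochs of 5 s = 50 s of data).
    """

    epoch_seconds: float = 5.0
    overlap_fraction: float = 0.8
    window: str = "hamming"
    min_epochs: int = 10

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.min_epochs < 1:
            raise ValueError("min_epochs must be at least 1")


@dataclass(frozen=True)
class Recording:
    """A single region-level time series with its sampling rate."""

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on a strictly increasing grid."""

    freqs: np.ndarray
    power: np.ndarray
    n_epochs: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape:
            raise ValueError("freqs and power must have the same shape")
        if freqs.size and np.any(np.diff(freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(power < 0):
            raise ValueError("power values must be nonnegative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


def segment_into_epochs(rec: Recording, cfg: SpectralConfig | None = None) -> np.ndarray:
    """Cut a recording into overlapping epochs.

    Returns a 2-D array of shape ``(n_epochs, epoch_len)``.  The epoch
    length and start-to-start step are rounded to whole samples; with the
    defaults (5 s, 80% overlap) at 500 samples/s the step is exactly
    500 samples, so epoch placement never drifts.  The number of epochs is
    ``floor((T - L) / step) + 1`` for T total and L epoch samples.
    """
    cfg = cfg or SpectralConfig()
    epoch_len = int(round(cfg.epoch_seconds * rec.fs))
    step = int(round(epoch_len * (1.0 - cfg.overlap_fraction)))
    if step < 1:
        raise ValueError(
            "overlap_fraction too high: epoch step is below one sample"
        )
    n = rec.samples.size
    if n < epoch_len:
        raise ValueError(
            f"recording of {n} samples is shorter than one "
            f"{epoch_len}-sample epoch"
        )
    n_epochs = (n - epoch_len) // step + 1
    starts = np.arange(n_epochs) * step
    return np.stack([rec.samples[s : s + epoch_len] for s in starts])


def enforce_minimum_epochs(epochs: np.ndarray, cfg: SpectralConfig | None = None) -> bool:
    """Gate on the minimum-epoch requirement (>= min_epochs passes)."""
    cfg = cfg or SpectralConfig()
    return len(epochs) >= cfg.min_epochs


def welch_psd(
    epochs: np.ndarray, fs: float, cfg: SpectralConfig | None = None, label: str = ""
) -> PowerSpectrum:
    """Average one-sided tapered periodograms over epochs.

    Each epoch is mean-removed, multiplied by the configured taper and
    transformed; periodograms use density normalization (power per Hz,
    ``|X|^2 / (fs * sum(w^2))``, doubled at interior bins) and are averaged
    pointwise.  No zero-padding is applied, so the bin spacing equals
    ``1 / epoch_seconds`` exactly.
    """
    cfg = cfg or SpectralConfig()
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.size == 0 or epochs.shape[0] == 0:
        raise ValueError("at least one epoch is required")
    n = epochs.shape[1]
    win = get_window(cfg.window, n)
    detrended = epochs - epochs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(detrended * win, axis=1)
    scale = 1.0 / (fs * np.sum(win**2))
    pxx = (np.abs(spec) ** 2) * scale
    # one-sided: double all bins except DC and (for even n) Nyquist
    if n % 2 == 0:
        pxx[:, 1:-1] *= 2.0
    else:
        pxx[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PowerSpectrum(
        freqs=freqs, power=pxx.mean(axis=0), n_epochs=epochs.shape[0], label=label
    )


def recording_psd(rec: Recording, cfg: SpectralConfig | None = None) -> PowerSpectrum:
    """Segment a recording and return its Welch PSD.

    Raises if the recording fails the minimum-epoch gate.
    """
    cfg = cfg or SpectralConfig()
    epochs = segment_into_epochs(rec, cfg)
    if not enforce_minimum_epochs(epochs, cfg):
        raise ValueError(
            f"recording '{rec.label}' yields {len(epochs)} epochs; "
            f"at least {cfg.min_epochs} are required"
        )
    return welch_psd(epochs, rec.fs, cfg, label=rec.label)
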