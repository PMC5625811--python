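"""Eight-band EEG power features.

A raw single-channel EEG segment is cut into consecutive, non-overlapping
1-second windows, each window is Hann-tapered and Fourier-transformed, and
the one-sided power spectrum (1 Hz bin spacing) is averaged within eight
fixed frequency bands:

    delta 1-3, theta 4-7, alpha1 8-10, alpha2 11-13,
    beta1 14-20, beta2 21-30, gamma1 31-40, gamma2 41-50 Hz

yielding one 8-vector of band powers per segment (mean over windows). The
band power is the classification feature for both the emotion-state and the
emotion-intensity classifiers.

Spectra use 'spectrum' scaling (power divided by the squared window sum), so
a unit-amplitude sinusoid contributes the same band power at any sampling
rate, and scaling the signal by c scales every feature by c**2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FrequencyBand",
    "EEGSegment",
    "BAND_NAMES",
    "band_edges",
    "stft_psd",
    "extract_features",
    "bandpass_filter",
]

BAND_NAMES = ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2", "gamma1", "gamma2")
_BAND_EDGES_HZ = ((1, 3), (4, 7), (8, 10), (11, 13), (14, 20), (21, 30), (31, 40), (41, 50))

#: Minimum sampling rate: the Nyquist frequency must cover the 41-50 Hz band
#: with a little headroom for the anti-alias transition of real recordings.
MIN_FS = 128


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, inclusive


def band_edges() -> list[FrequencyBand]:
    """The eight analysis bands, in feature-vector order."""
    return [FrequencyBand(n, lo, hi) for n, (lo, hi) in zip(BAND_NAMES, _BAND_EDGES_HZ)]


@dataclass
class EEGSegment:
    """A single-channel EEG time series.

    Parameters
    ----------
    samples
        Amplitude series, arbitrary units.
    fs
        Sampling rate in Hz; must be >= 128 so the gamma2 band is resolvable,
        and an integer so 1-s windows give exactly 1 Hz bin spacing.
    """

    samples: np.ndarray
    fs: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not float(self.fs).is_integer():
            raise ValueError(f"fs must be an integer number of Hz, got {self.fs}")
        self.fs = int(self.fs)
        if self.fs < MIN_FS:
            raise ValueError(f"fs must be >= {MIN_FS} Hz, got {self.fs}")
        if self.samples.size < self.fs:
            raise ValueError(
                f"segment too short: {self.samples.size} samples < one 1-s window ({self.fs})"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_windows(self) -> int:
        return self.samples.size // self.fs


def stft_psd(segment: EEGSegment) -> tuple[np.ndarray, np.ndarray]:
    """Per-window one-sided power spectra of non-overlapping 1-s Hann windows.

    Returns
    -------
    freqs : (fs//2 + 1,) array
        Frequency bins in Hz at exactly 1 Hz spacing (0 .. fs/2).
    psd : (n_windows, fs//2 + 1) array
        Power per bin for each window ('spectrum' scaling: amplitude-squared
        units, normalized by the squared Hann window sum; one-sided with the
        usual factor-2 doubling of interior bins).

    Trailing samples that do not fill a whole window are discarded.
    """
    fs = segment.fs
    n_win = segment.n_windows
    windows = segment.samples[: n_win * fs].reshape(n_win, fs)
    freqs, psd = signal.periodogram(
        windows, fs=fs, window="hann", scaling="spectrum", detrend=False, axis=1
    )
    return freqs, psd


def _band_slices(freqs: np.ndarray) -> list[np.ndarray]:
    return [
        (freqs >= band.lo) & (freqs <= band.hi)  # inclusive at both edges
        for band in band_edges()
    ]


def extract_features(segment: EEGSegment) -> np.ndarray:
    """Eight-band power feature vector of a segment.

    For each band the power bins inside [lo, hi] (inclusive) are averaged,
    then averaged across windows. Returns a (8,) array in the order of
    :data:`BAND_NAMES`. All entries are finite and >= 0.
    """
    freqs, psd = stft_psd(segment)
    per_window = np.stack([psd[:, m].mean(axis=1) for m in _band_slices(freqs)], axis=1)
    return per_window.mean(axis=0)


def windowed_features(segment: EEGSegment) -> np.ndarray:
    """Band-power features of each 1-s window separately, shape (n_windows, 8).

    One row per window; used when each window is a training sample for the
    classifiers and the segment-level decision averages window scores.
    """
    freqs, psd = stft_psd(segment)
    return np.stack([psd[:, m].mean(axis=1) for m in _band_slices(freqs)], axis=1)


def bandpass_filter(samples: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Optional zero-phase Butterworth band-pass preprocessing.

    Not part of the feature path (band powers are integrated directly from
    the windowed spectra); provided for callers who want a time-domain
    filtered trace, e.g. for plotting.
    """
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))
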