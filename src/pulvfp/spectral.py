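"""Morlet-wavelet power spectral density and baseline z-score normalization.

This module implements the first stage of the seizure-fingerprinting
pipeline: a complex Morlet time–frequency decomposition of an intracranial
EEG channel, per-frequency baseline statistics from a pre-ictal interval,
and z-score normalization of the spectrogram against that baseline.

The wavelet family is parameterized by the full width at half maximum
(FWHM) of its time-domain Gaussian envelope, anchored at a 1 Hz reference
frequency (default 3 s). In the default ``"scaled"`` mode the FWHM shrinks
inversely with frequency, i.e. the number of cycles under the envelope is
constant across the spectrum; ``"fixed"`` keeps the same time-domain FWHM
at every analysis frequency. Samples closer to either record edge than one
wavelet half-support are flagged as invalid (NaN) so that filter edge
transients never contaminate baseline statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "IEEGRecording",
    "WaveletParams",
    "WaveletSpectrogram",
    "BaselineStats",
    "NormalizedSpectrogram",
    "morlet_psd",
    "baseline_stats",
    "zscore_normalize",
    "default_freq_grid",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2*sqrt(2 ln 2) * sigma


@dataclass
class IEEGRecording:
    """Multichannel fixed-rate intracranial EEG segment.

    Samples are ``channels x time`` in physical units (microvolts by
    convention); times are measured in seconds from the record start.
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample vector for a channel label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.samples[idx]


def default_freq_grid(
    low_hz: float = 1.0, high_hz: float = 150.0, step_hz: float = 0.2
) -> np.ndarray:
    """Uniform analysis-frequency grid, inclusive of both edges.

    The default 1–150 Hz grid at 0.2 Hz spacing represents the band edges
    relevant to ictal fingerprinting (e.g. 9.4, 39.8, 61.8 Hz) exactly.
    """
    n = int(round((high_hz - low_hz) / step_hz))
    return low_hz + step_hz * np.arange(n + 1)


@dataclass
class WaveletParams:
    """Complex-Morlet analysis parameters.

    Parameters
    ----------
    freqs_hz
        Monotone increasing analysis frequencies (Hz).
    fwhm_s
        Time-domain FWHM of the Gaussian envelope at the 1 Hz reference
        frequency (seconds).
    fwhm_mode
        ``"scaled"``: FWHM(f) = fwhm_s / f (constant cycles).
        ``"fixed"``: FWHM(f) = fwhm_s at all frequencies.
    decim
        Decimation factor for the output time axis; power is averaged over
        non-overlapping blocks of ``decim`` input samples. Keeps long-record
        spectrograms in memory without losing band power.
    """

    freqs_hz: np.ndarray = field(default_factory=default_freq_grid)
    fwhm_s: float = 3.0
    fwhm_mode: str = "scaled"
    decim: int = 1

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.freqs_hz.ndim != 1 or self.freqs_hz.size == 0:
            raise ValueError("freqs_hz must be a non-empty 1-D array")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")
        if np.any(self.freqs_hz <= 0):
            raise ValueError("analysis frequencies must be positive")
        if self.fwhm_s <= 0:
            raise ValueError("fwhm_s must be positive")
        if self.fwhm_mode not in ("scaled", "fixed"):
            raise ValueError("fwhm_mode must be 'scaled' or 'fixed'")
        if int(self.decim) < 1:
            raise ValueError("decim must be >= 1")
        self.decim = int(self.decim)

    def fwhm_at(self, freq_hz: np.ndarray) -> np.ndarray:
        """Time-domain envelope FWHM (s) at each analysis frequency."""
        freq_hz = np.asarray(freq_hz, dtype=float)
        if self.fwhm_mode == "scaled":
            return self.fwhm_s / freq_hz
        return np.full_like(freq_hz, self.fwhm_s)

    def half_support_s(self, freq_hz: np.ndarray) -> np.ndarray:
        """Effective wavelet half-support (s): 3 envelope standard deviations."""
        sigma_t = self.fwhm_at(freq_hz) / _FWHM_TO_SIGMA
        return 3.0 * sigma_t


@dataclass
class WaveletSpectrogram:
    """Time x frequency wavelet power with axis metadata.

    ``power[t, f]`` is the squared magnitude of the analytic wavelet
    coefficient, normalized so a unit-amplitude sinusoid at an analysis
    frequency yields power 1 at that frequency. Edge-flagged samples are
    NaN.
    """

    power: np.ndarray
    times_s: np.ndarray
    freqs_hz: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        if self.power.shape != (self.times_s.size, self.freqs_hz.size):
            raise ValueError("power shape must be (n_times, n_freqs)")
        valid = self.power[np.isfinite(self.power)]
        if valid.size and valid.min() < 0:
            raise ValueError("power must be non-negative")

    def time_slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Boolean mask over the time axis for the half-open [start, end)."""
        return (self.times_s >= start_s) & (self.times_s < end_s)


@dataclass
class BaselineStats:
    """Per-frequency mean and spread of power over a baseline interval."""

    mean: np.ndarray
    sd: np.ndarray
    baseline_interval_s: tuple[float, float]
    n_samples: int
    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")


@dataclass
class NormalizedSpectrogram:
    """Baseline z-scored spectrogram: z = (power - mean) / sd per frequency."""

    z: np.ndarray
    times_s: np.ndarray
    freqs_hz: np.ndarray
    channel: str

    def time_slice(self, start_s: float, end_s: float) -> np.ndarray:
        return (self.times_s >= start_s) & (self.times_s < end_s)


def morlet_psd(
    recording: IEEGRecording, channel: str, params: WaveletParams
) -> WaveletSpectrogram:
    """Complex-Morlet wavelet power of one channel.

    The transform is computed as a frequency-domain Gaussian filter bank:
    the signal's FFT is multiplied, per analysis frequency f, by
    ``2 * exp(-(xi - f)^2 / (2 sigma_f^2))`` restricted to positive
    frequencies (an analytic Morlet with unit peak gain), and power is the
    squared magnitude of the inverse transform. With this normalization a
    unit-amplitude sinusoid at f produces power 1 at f.

    Samples within one wavelet half-support (3 envelope SDs) of either
    record edge are set to NaN, per frequency, so lower frequencies carry
    wider invalid margins. When ``params.decim > 1`` power is averaged over
    non-overlapping blocks of ``decim`` samples and a block is NaN if any
    contributing sample is edge-flagged.
    """
    x = recording.channel(channel)
    fs = recording.fs_hz
    nyq = fs / 2.0
    if params.freqs_hz[-1] >= nyq:
        raise ValueError(
            f"analysis frequency {params.freqs_hz[-1]} Hz is at or above "
            f"Nyquist ({nyq} Hz)"
        )
    n = x.size
    half_supp_s = params.half_support_s(params.freqs_hz)
    pad = int(np.ceil(half_supp_s.max() * fs)) + 1
    nfft = next_fast_len(n + 2 * pad)
    X = fft(x, nfft)
    xi = np.fft.fftfreq(nfft, d=1.0 / fs)
    pos = xi > 0

    decim = params.decim
    n_blocks = n // decim
    power = np.empty((n_blocks, params.freqs_hz.size))
    sigma_t = params.fwhm_at(params.freqs_hz) / _FWHM_TO_SIGMA
    sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
    for j, (f0, sf) in enumerate(zip(params.freqs_hz, sigma_f)):
        w = np.zeros(nfft)
        w[pos] = 2.0 * np.exp(-((xi[pos] - f0) ** 2) / (2.0 * sf**2))
        coef = ifft(X * w)[:n]
        p = np.abs(coef) ** 2
        margin = int(np.ceil(half_supp_s[j] * fs))
        if margin > 0:
            p[:margin] = np.nan
            p[n - margin :] = np.nan
        if decim == 1:
            power[:, j] = p
        else:
            blocks = p[: n_blocks * decim].reshape(n_blocks, decim)
            power[:, j] = blocks.mean(axis=1)  # NaN if any sample flagged

    if decim == 1:
        times = recording.start_time_s + np.arange(n) / fs
    else:
        times = recording.start_time_s + (np.arange(n_blocks) + 0.5) * decim / fs
    return WaveletSpectrogram(
        power=power, times_s=times, freqs_hz=params.freqs_hz.copy(), channel=channel
    )


def baseline_stats(
    spec: WaveletSpectrogram,
    interval_s: tuple[float, float],
    min_duration_s: float = 0.0,
    annotations=None,
) -> BaselineStats:
    """Per-frequency mean and sample SD of power over a baseline interval.

    Edge-flagged (NaN) samples are excluded per frequency. The sample
    standard deviation uses ddof=1. If ``annotations`` is given, the
    interval must not overlap any annotated seizure on the spectrogram's
    channel.
    """
    start, end = interval_s
    if end - start < min_duration_s:
        raise ValueError(
            f"baseline interval {end - start:.1f} s shorter than required "
            f"{min_duration_s:.1f} s"
        )
    if annotations is not None:
        for ann in annotations:
            if ann.channel == spec.channel and ann.onset_s < end and ann.offset_s > start:
                raise ValueError(
                    f"baseline interval ({start}, {end}) overlaps seizure "
                    f"[{ann.onset_s}, {ann.offset_s}] on {spec.channel}"
                )
    mask = spec.time_slice(start, end)
    if not mask.any():
        raise ValueError(f"baseline interval ({start}, {end}) contains no samples")
    block = spec.power[mask]
    n_valid = np.sum(np.isfinite(block), axis=0)
    if np.any(n_valid < 2):
        f_bad = spec.freqs_hz[int(np.argmin(n_valid))]
        raise ValueError(
            f"fewer than 2 valid baseline samples at {f_bad:.2f} Hz "
            "(interval lies inside the edge-flagged margin)"
        )
    mean = np.nanmean(block, axis=0)
    sd = np.nanstd(block, axis=0, ddof=1)
    return BaselineStats(
        mean=mean,
        sd=sd,
        baseline_interval_s=(start, end),
        n_samples=int(mask.sum()),
        freqs_hz=spec.freqs_hz.copy(),
    )


def zscore_normalize(
    spec: WaveletSpectrogram, stats: BaselineStats
) -> NormalizedSpectrogram:
    """z-score the spectrogram against baseline statistics, per frequency."""
    if spec.freqs_hz.shape != stats.freqs_hz.shape or not np.allclose(
        spec.freqs_hz, stats.freqs_hz
    ):
        raise ValueError("spectrogram and baseline frequency axes differ")
    zero = np.flatnonzero(stats.sd == 0)
    if zero.size:
        raise ValueError(
            "degenerate baseline (sd = 0) at "
            f"{spec.freqs_hz[zero[0]]:.2f} Hz"
        )
    z = (spec.power - stats.mean[None, :]) / stats.sd[None, :]
    return NormalizedSpectrogram(
        z=z, times_s=spec.times_s.copy(), freqs_hz=spec.freqs_hz.copy(),
        channel=spec.channel,
    )
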