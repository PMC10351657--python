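"""Two-level spectral fingerprint selection.

Level 1 finds statistically significant ictal frequency bands: per
analysis frequency, the baseline-normalized ictal power is summarized
over ictal time samples (median by default) and contiguous runs exceeding
a z threshold (default 3.3, about the 99.9th percentile of a standard
normal one-sided) become candidate bands.

Level 2 emulates the constraint of a sensing device that can store only a
single 5-Hz band: a 5-Hz bin slides across each significant band in fine
steps, each bin is scored by the mean summary z over its frequencies,
averaged across seizures, and the best-scoring bin is the "spectral
fingerprint" deployed for detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import NormalizedSpectrogram

__all__ = [
    "FrequencyBand",
    "BinScore",
    "FingerprintParams",
    "FingerprintResult",
    "significant_bands",
    "scan_bins",
    "select_fingerprint",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency interval [low_hz, high_hz)."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.high_hz <= self.low_hz:
            raise ValueError("high_hz must exceed low_hz")
        if self.low_hz <= 0:
            raise ValueError("low_hz must be positive")

    @property
    def center_hz(self) -> float:
        return (self.low_hz + self.high_hz) / 2.0

    @property
    def width_hz(self) -> float:
        return self.high_hz - self.low_hz

    def contains(self, freqs_hz: np.ndarray) -> np.ndarray:
        return (freqs_hz >= self.low_hz - 1e-9) & (freqs_hz < self.high_hz - 1e-9)


@dataclass
class FingerprintParams:
    """Thresholds and geometry of the two-level scan.

    Defaults follow the analysis this package reproduces: z > 3.3 for band
    significance, 5-Hz bins sliding in 0.05 Hz steps, and a minimum band
    width of 1 Hz to discard isolated supra-threshold frequencies.
    """

    z_threshold: float = 3.3
    bin_width_hz: float = 5.0
    bin_step_hz: float = 0.05
    min_band_width_hz: float = 1.0
    ictal_summary: str = "median"  # median | mean | max over ictal time samples

    def __post_init__(self) -> None:
        for name in ("z_threshold", "bin_width_hz", "bin_step_hz", "min_band_width_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ictal_summary not in ("median", "mean", "max"):
            raise ValueError("ictal_summary must be 'median', 'mean' or 'max'")


@dataclass
class BinScore:
    """Score of one candidate 5-Hz bin: mean ictal z, per seizure and pooled."""

    band: FrequencyBand
    score: float
    per_seizure_scores: list[float]


@dataclass
class FingerprintResult:
    """Full provenance of a fingerprint selection."""

    significant_bands: list[FrequencyBand]
    bin_scores: list[BinScore]
    selected: FrequencyBand
    selected_score: float
    params: FingerprintParams


def _summarize_ictal(
    norm: NormalizedSpectrogram,
    interval_s: tuple[float, float],
    summary: str,
) -> np.ndarray:
    """Collapse the time axis over the ictal interval: one z per frequency."""
    start, end = interval_s
    mask = norm.time_slice(start, end)
    if not mask.any():
        raise ValueError(f"ictal interval ({start}, {end}) contains no samples")
    block = norm.z[mask]
    fn = {"median": np.nanmedian, "mean": np.nanmean, "max": np.nanmax}[summary]
    with np.errstate(all="ignore"):
        return fn(block, axis=0)


def significant_bands(
    norm: NormalizedSpectrogram,
    seizure_interval_s: tuple[float, float],
    params: FingerprintParams,
) -> list[FrequencyBand]:
    """Contiguous frequency runs whose summary ictal z exceeds the threshold.

    Band edges snap to the analysis grid: a run of grid frequencies
    f_i..f_j maps to the half-open band [f_i, f_j + step). Runs narrower
    than ``min_band_width_hz`` are discarded.
    """
    summary_z = _summarize_ictal(norm, seizure_interval_s, params.ictal_summary)
    return bands_from_summary(summary_z, norm.freqs_hz, params)


def bands_from_summary(
    summary_z: np.ndarray, freqs_hz: np.ndarray, params: FingerprintParams
) -> list[FrequencyBand]:
    """Threshold a per-frequency summary z into grid-snapped bands."""
    if freqs_hz.size == 0:
        raise ValueError("no frequencies")
    if freqs_hz.size > 1:
        step = float(np.median(np.diff(freqs_hz)))
    else:
        step = params.min_band_width_hz
    above = np.asarray(summary_z) > params.z_threshold
    bands: list[FrequencyBand] = []
    i = 0
    n = above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        band = FrequencyBand(float(freqs_hz[i]), float(freqs_hz[j] + step))
        if band.width_hz >= params.min_band_width_hz - 1e-9:
            bands.append(band)
        i = j + 1
    return bands


def scan_bins(
    norms: list[NormalizedSpectrogram],
    intervals_s: list[tuple[float, float]],
    bands: list[FrequencyBand],
    params: FingerprintParams,
) -> list[BinScore]:
    """Slide a bin of ``bin_width_hz`` over each band and score every placement.

    Bins start at the band's low edge and advance by ``bin_step_hz`` while
    remaining fully inside the band. A bin's per-seizure score is the mean
    summary ictal z over grid frequencies inside [low, low + width); the
    pooled score is the unweighted mean across seizures. Bands narrower
    than the bin width contribute no bins.
    """
    if not norms:
        raise ValueError("at least one seizure spectrogram required")
    if len(norms) != len(intervals_s):
        raise ValueError("one ictal interval per spectrogram required")
    if not bands:
        raise ValueError("no significant bands to scan")
    freqs = norms[0].freqs_hz
    for norm in norms[1:]:
        if not np.allclose(norm.freqs_hz, freqs):
            raise ValueError("all spectrograms must share one frequency axis")
    summaries = np.vstack(
        [
            _summarize_ictal(norm, iv, params.ictal_summary)
            for norm, iv in zip(norms, intervals_s)
        ]
    )

    scores: list[BinScore] = []
    for band in bands:
        if band.width_hz < params.bin_width_hz - 1e-9:
            logger.warning(
                "band %.2f-%.2f Hz narrower than bin width %.2f Hz; skipped",
                band.low_hz, band.high_hz, params.bin_width_hz,
            )
            continue
        n_steps = int(
            np.floor((band.width_hz - params.bin_width_hz) / params.bin_step_hz + 1e-9)
        )
        for k in range(n_steps + 1):
            low = band.low_hz + k * params.bin_step_hz
            bin_band = FrequencyBand(low, low + params.bin_width_hz)
            in_bin = bin_band.contains(freqs)
            if not in_bin.any():
                continue
            per_seizure = np.nanmean(summaries[:, in_bin], axis=1)
            scores.append(
                BinScore(
                    band=bin_band,
                    score=float(np.mean(per_seizure)),
                    per_seizure_scores=[float(v) for v in per_seizure],
                )
            )
    scores.sort(key=lambda s: s.band.center_hz)
    return scores


def select_fingerprint(
    scores: list[BinScore],
    significant: list[FrequencyBand] | None = None,
    params: FingerprintParams | None = None,
) -> FingerprintResult:
    """Pick the best-scoring bin; ties break toward the lower center frequency."""
    if not scores:
        raise ValueError("no bin scores to select from")
    best = scores[0]
    for s in scores[1:]:
        if s.score > best.score:  # strict: earlier (lower-center) bin wins ties
            best = s
    return FingerprintResult(
        significant_bands=list(significant or []),
        bin_scores=scores,
        selected=best.band,
        selected_score=best.score,
        params=params or FingerprintParams(),
    )
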