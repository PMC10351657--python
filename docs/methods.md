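# Methods

This note documents the models, parameter choices and numerical decisions
behind `pulvfp`, and what its synthetic experiments do and do not
establish about real recordings.

## Problem setting

A patient implanted with a sensing DBS device in the bilateral pulvinar
can be monitored ambulatorily only through a severely compressed channel:
one band-power value per 10-minute window, in a single 5-Hz band chosen at
programming time. The package answers two questions: (1) from annotated
stereo-EEG seizures, which 5-Hz band best separates ictal from interictal
power; (2) given that band, how reliably do threshold crossings of the
windowed power-in-band timeline reproduce the patient's seizure diary,
including left/right lateralization.

## Wavelet transform

The time–frequency decomposition is a complex Morlet filter bank applied
in the frequency domain: the signal's FFT is multiplied per analysis
frequency f by a Gaussian `2·exp(−(ξ−f)²/2σ_f²)` restricted to positive
frequencies, and power is the squared magnitude of the inverse transform.

- **Parameterization.** The family is anchored by the time-domain envelope
  FWHM at a 1 Hz reference (default 3 s). Two modes:
  - `scaled` (default): FWHM(f) = 3 s / f — constant cycle count
    (≈ 8 cycles), the usual choice for broadband spectrograms;
  - `fixed`: FWHM(f) = 3 s at every frequency — constant spectral
    bandwidth (σ_f ≈ 0.125 Hz).
  The two modes are genuinely different readings of a
  "3-second-FWHM Morlet" specification; both are first-class and tested.
- **Normalization** is amplitude-preserving: a unit sinusoid at an
  analysis frequency yields power 1. A consequence worth knowing: in
  `scaled` mode the wavelet's noise-equivalent bandwidth grows ∝ f, so for
  1/f-PSD noise the measured power is approximately flat in f, whereas in
  `fixed` mode it tracks the PSD. Since every downstream statistic is
  z-scored per frequency against a baseline, this choice does not affect
  band significance or bin scores — it only changes the units of raw
  power.
- **Edge handling.** Per frequency, samples within 3 envelope SDs of
  either record end are set to NaN rather than silently zero-padded; all
  baseline and ictal statistics are NaN-aware. This keeps filter
  transients out of the baseline.
- **Decimation.** For long records the power time axis is averaged over
  non-overlapping blocks (default 25 samples → 0.1 s at 250 Hz) purely to
  bound memory; block averaging is power-conserving.
- **Frequency grid.** Default 1–150 Hz at 0.2 Hz, which represents the
  relevant band edges (9.4, 12.15, 39.8, 61.8 Hz) exactly. The pipeline
  clips the grid below Nyquist for low sampling rates.

## Baseline and z-scoring

Per-frequency mean and *sample* SD (ddof = 1) over a pre-ictal interval,
900 s by default, which must not overlap any annotated seizure. A zero SD
anywhere is an error naming the frequency — it indicates a degenerate
(e.g. constant or synthetic-silence) baseline rather than something to
silently patch.

## Two-level fingerprint

- The time dimension is collapsed with the **median** ictal z per
  frequency (mean and max are config options). The median is robust to
  brief artifacts and to the heavy right tail of wavelet power.
- Bands are maximal contiguous grid runs with summary z > 3.3, snapped to
  the grid ([first, last + step)), discarded below 1 Hz width. When
  several seizures are analyzed, each seizure's bands are computed
  separately and merged by union before scanning.
- Bins of exactly 5 Hz slide in 0.05-Hz steps, fully inside a band; a
  bin's score is the mean summary z over its frequencies, averaged
  across seizures without weighting. Ties break toward the lower center
  frequency; output ordering is by center. An exhaustive brute-force
  enumeration reproduces the scan bit-for-bit in the test suite.

## Detection

- **FIR mode** (SEEG analysis): Hamming-window linear-phase bandpass with
  a 1 Hz transition band (tap count = 3.3·f_s/transition, odd), applied
  forward-backward for zero phase; the squared output is averaged over
  non-overlapping windows. The 1 Hz transition keeps the filter's
  effective noise bandwidth close to the nominal 5-Hz bin; with a wider
  transition the FIR timeline systematically over-collects 1/f background
  from below the band and its window ranks decouple from the FFT mode's.
- **FFT (Percept) mode**: per window, a rectangular-window periodogram
  scaled so all bins sum to the window's mean square (Parseval); the
  stored value is the sum over [low, high). Input is resampled to 250 Hz
  if needed. This mirrors a device that "computes the Fourier transform
  of the 10-minute signal and stores only the relevant frequency band".
- **Thresholding**: window z against a baseline that can be (a) robust —
  median and 1.4826·MAD over the whole timeline (default; tolerates rare
  seizure windows without ground truth), (b) the first k windows, (c) an
  explicit seizure-free interval, or (d) a stored (mean, SD) pair, as when
  device data are scored against statistics learned during monitoring.
  Windows with z > 5 are detections; runs of consecutive detections
  (bridging up to `merge_gap_windows` dropouts) merge into one event
  reported at the run's first window. A plain power-ratio criterion
  (value > k·mean) is available as `threshold_mode="ratio"`, since
  "5× baseline power" and "z > 5" are different statistics.
- **Evaluation**: greedy one-to-one matching of events to diary intervals
  within ± one window by default; unmatched events are false positives.
- A subtlety the property tests encode: because consecutive supra-threshold
  windows merge, raising the threshold can *split* a merged run and thus
  increase the raw event count on adversarial timelines. Event counts are
  monotone in the threshold on realistic (unimodal-background) data, and
  the set of supra-threshold windows is always monotone.

## Synthetic data: what it emulates, and what it does not

The generator plants, on independent-channel 1/f^1 Gaussian backgrounds
(default RMS 20 μV, a typical depth-LFP scale), seizures consisting of:

- a narrowband ictal rhythm: white noise spectrally shaped to
  [center − bw/2, center + bw/2] (default 14.65 ± 2.5 Hz), scaled to
  `ictal_amplitude` × background RMS (default 3), with 2-s cosine ramps
  and an optional linear chirp;
- an optional broadband high-frequency component over 61.8–150 Hz
  (clipped at Nyquist), default amplitude 0 in the type and 0.3× in the
  study recipes — strong enough to be visible in wavelet z, weak enough
  that a 5-Hz control band overlapping its lower edge stays below the
  detection threshold, consistent with a negative control band showing
  nothing.

Injection is strictly confined to the annotated interval and channel;
everything else is bit-identical to the background, which is what makes
the laterality and conservation tests exact.

**Study recipes** (`emu_study_config`, `ambulatory_study_config`) scale a
week of monitoring down to desktop sizes while keeping every analysis
parameter at its reference value: one hour at 250 Hz with three
left-sided 90-s seizures (15-min baselines, 10-s detection windows
standing in for 10-min device windows, 360 windows total), and two hours
with five left-sided seizures detected in FFT mode with 30-s windows.
Scaling the window length is legitimate because both the band-power
statistic and its z-score are per-window quantities; only the number of
degrees of freedom per window changes.

What passing these experiments does **not** show: performance on real
seizures (whose rhythms drift, start focally, and co-occur with
artifacts), robustness to electrode impedance changes or circadian power
drift in months-long timelines, or behavior under overlapping bilateral
seizures. The generator is spectrally faithful but morphologically naive
by design.

A known, measured bias: with the default scaled wavelets, dividing ictal
power by a 1/f-shaped baseline SD tilts the z-profile slightly toward
higher frequencies, so the recovered bin center sits ~0.3 Hz above the
planted 14.65 Hz (14.95 Hz across seeds) — well inside the ±0.5 Hz
recovery tolerance, and a real property of z-scored fingerprinting on
1/f backgrounds rather than an implementation artifact.

## Numerical and interface choices

- Times are seconds from record start; bands are half-open [low, high) Hz;
  channels are addressed by label (`LEFT_PULV`, `RIGHT_PULV`).
- EDF is the signal container (16-bit, 1-s records, physical units μV,
  fixed header timestamps so identical data give identical bytes);
  reading goes through `mne`, writing through the package's own minimal
  writer. Round trips are exact to one quantization step.
- All randomness flows from explicit integer seeds; every pipeline
  artifact embeds the config and package version and no timestamps, so
  reruns are byte-identical.
- Degenerate inputs fail loudly (zero baseline SD, intervals inside edge
  margins, overlapping seizures, bands above Nyquist) — with one
  documented exception: a perfectly flat timeline yields no events rather
  than an error, since nothing can cross any threshold.
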