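# pulvfp

Seizure **spectral fingerprinting** and ambulatory **power-in-band
detection** for pulvinar intracranial EEG.

Sensing-enabled deep-brain stimulators (e.g. the Medtronic Percept in its
BrainSense Timeline mode) cannot stream raw electrophysiology: they store a
single number per 10-minute window — the spectral power of the 250 Hz local
field potential inside one programmable 5-Hz band. Turning such a device
into an ambulatory seizure diary therefore requires choosing, from a
patient's stereo-EEG monitoring data, the one 5-Hz band whose power best
discriminates seizures from the interictal state. `pulvfp` implements that
workflow end to end for bilateral pulvinar recordings, together with a
seeded synthetic iEEG generator so the whole pipeline is testable without
patient data.

## Method

Given an iEEG channel x(t) sampled at f_s and a set of annotated seizures:

1. **Wavelet PSD.** Complex Morlet time–frequency power
   P(t, f) = |(x ∗ ψ_f)(t)|², with the wavelet family parameterized by the
   time-domain envelope FWHM (3 s at the 1 Hz reference, scaling as 1/f so
   the cycle count is constant; a fixed-FWHM mode is available). Samples
   within one wavelet half-support of the record edges are masked.
2. **Baseline z-scoring.** For each seizure, per-frequency mean μ(f) and
   sample SD σ(f) over a 15-min pre-ictal baseline give
   z(t, f) = (P(t, f) − μ(f)) / σ(f).
3. **Significant bands.** The median of z(t, f) over ictal samples is
   thresholded at z > 3.3; maximal contiguous frequency runs (≥1 Hz wide)
   are the candidate bands.
4. **5-Hz bin scan.** A bin of width 5 Hz slides over each band in 0.05-Hz
   steps; each placement is scored by the mean summary z over its
   frequencies, averaged across seizures. The arg-max bin is the
   **spectral fingerprint** (ties break toward the lower center).
5. **Detection.** Band power per non-overlapping 10-min window, either by
   zero-phase FIR bandpass + mean square (SEEG analysis mode) or by a
   per-window FFT band sum (Percept BrainSense emulation). Windows with
   z > 5 against a baseline (robust median/MAD by default) are detection
   events, merged across consecutive windows, with laterality given by the
   channel. Events are scored against the seizure diary by greedy
   one-to-one interval matching.

The synthetic generator plants, on a 1/f background, band-limited Gaussian
ictal oscillations (default centered at 14.65 Hz, 5 Hz wide, 3× background
RMS) plus an optional broadband high-frequency component, with cosine
on/off ramps and exact ground-truth annotations.

## Worked example

```bash
python examples/02_fingerprint_scan.py
```

```
significant bands (median ictal z > 3.3):
   10.40 -  21.60 Hz
selected 5-Hz bin : 12.45 - 17.45 Hz (center 14.95 Hz)
bin score         : 169.4 (mean ictal z across seizures; the planted center was 14.65 Hz)
```

Two synthetic seizures carrying a 14.65-Hz rhythm produce one significant
low-beta band; the sliding bin scan localizes the fingerprint bin to
within a few tenths of a hertz of the planted center, with a mean ictal
z-score of ~170 inside the bin. Deploying that band for detection
(`examples/03_emu_detection.py`) finds all three seizures of the one-hour
EMU analog with zero false positives across 360 windows, and the
Percept-mode emulation (`examples/04_ambulatory_percept.py`) detects all
five seizures of a two-hour ambulatory record, all lateralized to the left
channel, with none on the right.

The same workflow is available as a shell pipeline:

```bash
pulvfp all --config cfg.yaml --outdir out/   # simulate → fingerprint → detect → evaluate
```

writing EDF, CSV and JSON artifacts (see `pulvfp.io` for the schemas).

## Layout

- `src/pulvfp/synthetic.py` — seeded two-channel iEEG generator
- `src/pulvfp/spectral.py` — Morlet PSD, baseline stats, z-normalization
- `src/pulvfp/fingerprint.py` — significant bands, 5-Hz bin scan, selection
- `src/pulvfp/detection.py` — FIR/FFT band-power timelines, z > 5 events,
  diary evaluation
- `src/pulvfp/pipeline.py`, `io.py`, `cli.py` — config, stage runner,
  readers/writers, `pulvfp` CLI
- `examples/` — one narrative script per capability
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
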