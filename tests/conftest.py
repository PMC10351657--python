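"""Shared fixtures and scaled study helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pulvfp import (
    LEFT,
    FingerprintParams,
    PipelineConfig,
    SeizureSpec,
    SyntheticConfig,
    WaveletParams,
    default_freq_grid,
    fingerprint_recording,
    generate_emu_dataset,
)
from pulvfp.pipeline import emu_study_config


def scaled_fingerprint_config(
    seed: int,
    ictal_amplitude: float = 3.0,
    ictal_center_hz: float = 14.65,
    duration_s: float = 660.0,
    onsets_s: tuple[float, ...] = (200.0, 430.0),
    seizure_duration_s: float = 60.0,
) -> PipelineConfig:
    """Minutes-scale analog of the fingerprint study: short record, short
    baseline, coarse low-frequency grid — fast enough for seed sweeps."""
    specs = [
        SeizureSpec(
            onset_s=t,
            duration_s=seizure_duration_s,
            channel=LEFT,
            ictal_center_hz=ictal_center_hz,
            ictal_amplitude=ictal_amplitude,
            hfo_amplitude=0.0,
        )
        for t in onsets_s
    ]
    return PipelineConfig(
        synthetic=SyntheticConfig(duration_s=duration_s, seizure_specs=specs, seed=seed),
        wavelet=WaveletParams(freqs_hz=default_freq_grid(2.0, 40.0, 0.2), decim=25),
        fingerprint=FingerprintParams(),
        baseline_duration_s=120.0,
        detection_window_s=10.0,
    )


def run_scaled_fingerprint(seed: int, **kwargs):
    cfg = scaled_fingerprint_config(seed, **kwargs)
    rec, anns = generate_emu_dataset(cfg.synthetic)
    result = fingerprint_recording(
        rec,
        anns,
        wavelet=cfg.wavelet,
        params=cfg.fingerprint,
        baseline_duration_s=cfg.baseline_duration_s,
    )
    return result, rec, anns


@pytest.fixture(scope="session")
def emu_dataset():
    """One scaled EMU record with three left-channel seizures (seed 7)."""
    cfg = scaled_fingerprint_config(seed=7)
    rec, anns = generate_emu_dataset(cfg.synthetic)
    return cfg, rec, anns


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
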