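"""Readers and writers for the pipeline's on-disk artifacts.

Formats: EDF for signals (written by :mod:`pulvfp._edf`, read back through
mne), CSV for seizure annotations and detection events, JSON for
fingerprint results, band-power timelines (a device-report-like schema
documented here, not a vendor format) and evaluation reports.
All times are seconds from record start; bands are half-open [low, high)
in Hz; channels are referenced by label.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from .detection import BandPowerTimeline, DetectionEvent, EvaluationReport
from .fingerprint import BinScore, FingerprintParams, FingerprintResult, FrequencyBand
from .spectral import IEEGRecording
from .synthetic import SeizureAnnotation

__all__ = [
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "write_fingerprint_json",
    "read_fingerprint_json",
    "write_timeline_json",
    "read_timeline_json",
    "write_events_csv",
    "read_events_csv",
    "write_report_json",
]

ANNOTATION_COLUMNS = ["onset_s", "offset_s", "channel", "label"]
EVENT_COLUMNS = ["window_index", "time_s", "z", "channel"]


def write_edf(recording: IEEGRecording, path) -> None:
    """Write a recording to EDF, one 16-bit signal per channel, units uV."""
    _edf.write_edf(
        path, recording.samples, recording.fs_hz, recording.channel_labels
    )


def read_edf(path) -> IEEGRecording:
    """Read an EDF file into an in-memory recording (physical units, uV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data(units="uV")
    return IEEGRecording(
        samples=samples,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def write_annotations(annotations: list[SeizureAnnotation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_s": a.onset_s,
                "offset_s": a.offset_s,
                "channel": a.channel,
                "label": a.label,
            }
            for a in sorted(annotations, key=lambda a: a.onset_s)
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_annotations(path, known_channels: list[str] | None = None
                     ) -> list[SeizureAnnotation]:
    """Read a seizure-annotation CSV; validates intervals and channel labels."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    annotations = []
    for i, row in df.iterrows():
        if row["offset_s"] <= row["onset_s"]:
            raise ValueError(
                f"annotation row {i}: offset_s ({row['offset_s']}) must exceed "
                f"onset_s ({row['onset_s']})"
            )
        channel = str(row["channel"])
        if known_channels is not None and channel not in known_channels:
            raise ValueError(
                f"annotation row {i}: unknown channel {channel!r} "
                f"(known: {known_channels})"
            )
        annotations.append(
            SeizureAnnotation(
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                channel=channel,
                label=str(row.get("label", "seizure")),
            )
        )
    return sorted(annotations, key=lambda a: a.onset_s)


def _band_dict(band: FrequencyBand) -> dict:
    return {"low_hz": band.low_hz, "high_hz": band.high_hz}


def write_fingerprint_json(result: FingerprintResult, path, provenance: dict
                           | None = None) -> None:
    payload = {
        "selected": _band_dict(result.selected),
        "selected_center_hz": result.selected.center_hz,
        "selected_score": result.selected_score,
        "significant_bands": [_band_dict(b) for b in result.significant_bands],
        "params": asdict(result.params),
        "bin_scores": [
            {
                "low_hz": s.band.low_hz,
                "high_hz": s.band.high_hz,
                "score": s.score,
                "per_seizure_scores": s.per_seizure_scores,
            }
            for s in result.bin_scores
        ],
    }
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_fingerprint_json(path) -> FingerprintResult:
    payload = json.loads(Path(path).read_text())
    params = FingerprintParams(**payload["params"])
    scores = [
        BinScore(
            band=FrequencyBand(s["low_hz"], s["high_hz"]),
            score=s["score"],
            per_seizure_scores=list(s["per_seizure_scores"]),
        )
        for s in payload["bin_scores"]
    ]
    return FingerprintResult(
        significant_bands=[
            FrequencyBand(b["low_hz"], b["high_hz"])
            for b in payload["significant_bands"]
        ],
        bin_scores=scores,
        selected=FrequencyBand(**payload["selected"]),
        selected_score=payload["selected_score"],
        params=params,
    )


def write_timeline_json(timeline: BandPowerTimeline, path) -> None:
    """Device-report-style timeline export (our schema, documented here)."""
    payload = {
        "band_low_hz": timeline.band.low_hz,
        "band_high_hz": timeline.band.high_hz,
        "window_s": timeline.window_s,
        "t0_s": timeline.t0_s,
        "channel": timeline.channel,
        "mode": timeline.mode,
        "values": [float(v) for v in timeline.values],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_timeline_json(path) -> BandPowerTimeline:
    payload = json.loads(Path(path).read_text())
    return BandPowerTimeline(
        values=np.asarray(payload["values"], dtype=float),
        window_s=payload["window_s"],
        band=FrequencyBand(payload["band_low_hz"], payload["band_high_hz"]),
        channel=payload["channel"],
        t0_s=payload["t0_s"],
        mode=payload["mode"],
    )


def write_events_csv(events: list[DetectionEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "window_index": e.window_index,
                "time_s": e.time_s,
                "z": e.z,
                "channel": e.channel,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_events_csv(path) -> list[DetectionEvent]:
    df = pd.read_csv(path)
    return [
        DetectionEvent(
            window_index=int(r["window_index"]),
            time_s=float(r["time_s"]),
            z=float(r["z"]),
            channel=str(r["channel"]),
        )
        for _, r in df.iterrows()
    ]


def write_report_json(report: EvaluationReport, path) -> None:
    payload = {
        "n_true": report.n_true,
        "n_detected": report.n_detected,
        "n_false_positive": report.n_false_positive,
        "tolerance_windows": report.tolerance_windows,
        "matches": [
            {
                "annotation": {
                    "onset_s": ann.onset_s,
                    "offset_s": ann.offset_s,
                    "channel": ann.channel,
                    "label": ann.label,
                },
                "event": {
                    "window_index": ev.window_index,
                    "time_s": ev.time_s,
                    "z": ev.z,
                    "channel": ev.channel,
                },
            }
            for ann, ev in report.matches
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
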