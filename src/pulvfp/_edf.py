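"""Minimal EDF (European Data Format) writer.

Writes plain 16-bit EDF with one signal per channel, a 1-second data
record, and per-channel physical scaling spanning the observed amplitude
range. Reading goes through mne (see :mod:`pulvfp.io`), which also serves
as an independent check of this writer's conformance. Header timestamps
are fixed so that identical recordings produce byte-identical files.
"""

from __future__ import annotations

import warnings

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num_str(value: float, width: int = 8) -> str:
    for prec in range(7, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot encode {value} in {width} EDF bytes")


def write_edf(
    path,
    samples: np.ndarray,
    fs_hz: float,
    channel_labels: list[str],
    physical_dimension: str = "uV",
) -> None:
    """Write channels x time samples to an EDF file.

    ``fs_hz`` must be an integer (samples per 1-second data record). A
    trailing partial second is truncated with a warning.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be channels x time")
    if abs(fs_hz - round(fs_hz)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs_hz))
    n_ch, n = samples.shape
    n_records = n // spr
    if n_records * spr != n:
        warnings.warn(
            f"truncating trailing {n - n_records * spr} samples (partial "
            "EDF data record)", stacklevel=2,
        )
        samples = samples[:, : n_records * spr]
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF data record")

    pmins, pmaxs, digital = [], [], []
    for ch in range(n_ch):
        x = samples[ch]
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 0.5, hi + 0.5
        # widen slightly, then encode edges at header precision and reuse
        # the *encoded* values for digitization so read-back scaling is exact
        span = hi - lo
        lo = float(_num_str(lo - 0.005 * span))
        hi = float(_num_str(hi + 0.005 * span))
        while hi <= x.max() or lo >= x.min():  # guard against rounding inward
            lo, hi = float(_num_str(lo - 0.01 * span)), float(_num_str(hi + 0.01 * span))
        gain = (DIG_MAX - DIG_MIN) / (hi - lo)
        d = np.round((x - lo) * gain + DIG_MIN).astype("<i2")
        pmins.append(lo)
        pmaxs.append(hi)
        digital.append(d)

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("EDF", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in channel_labels),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(physical_dimension, 8) for _ in range(n_ch)),
            b"".join(_field(_num_str(pmins[c]), 8) for c in range(n_ch)),
            b"".join(_field(_num_str(pmaxs[c]), 8) for c in range(n_ch)),
            b"".join(_field(str(DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch][r * spr : (r + 1) * spr].tobytes())


def quantization_step(samples: np.ndarray) -> float:
    """Worst-case physical value of one digital unit for these samples."""
    samples = np.asarray(samples, dtype=float)
    spans = samples.max(axis=1) - samples.min(axis=1)
    span = float(spans.max()) if spans.size else 1.0
    span = max(span, 1.0e-12)
    return span / (DIG_MAX - DIG_MIN)
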