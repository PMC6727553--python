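"""Minimal EDF (European Data Format) reader and writer.

Implements the fixed-layout 16-bit EDF container: a 256-byte global header,
256 bytes of per-signal header fields, then data records of little-endian
int16 samples, one contiguous block per signal per record.  Multi-rate
files are handled natively — each signal keeps its own samples-per-record,
and reading never resamples.

Only the subset needed for two-channel polysomnography is supported:
continuous recordings, one-second data records, no annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class EdfChannel:
    label: str
    rate: float
    samples: np.ndarray
    phys_min: float = -1000.0
    phys_max: float = 1000.0


class EdfError(ValueError):
    """Raised for structurally invalid EDF files."""


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(path: str | Path, channels: list[EdfChannel], record_s: float = 1.0) -> None:
    """Write channels to an EDF file with ``record_s``-second data records.

    Each channel's samples-per-record must be integral (rate × record_s);
    trailing samples that do not fill a whole record are zero-padded so the
    written duration is ``ceil(duration / record_s)`` records.
    """
    path = Path(path)
    spr = []
    for ch in channels:
        n = ch.rate * record_s
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise EdfError(f"rate {ch.rate} not integral per {record_s}-s record")
        spr.append(int(round(n)))
    n_records = max(
        math.ceil(len(ch.samples) / n) if len(ch.samples) else 0
        for ch, n in zip(channels, spr)
    )
    ns = len(channels)

    header = b"".join([
        _field("0", 8),
        _field("ratsleep", 80),
        _field("synthetic recording", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + ns)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field(f"{record_s:g}", 8),
        _field(str(ns), 4),
    ])

    def sig_fields(getter, width):
        return b"".join(_field(getter(ch, n), width) for ch, n in zip(channels, spr))

    header += sig_fields(lambda ch, n: ch.label, 16)
    header += sig_fields(lambda ch, n: "", 80)            # transducer
    header += sig_fields(lambda ch, n: "uV", 8)           # physical dimension
    header += sig_fields(lambda ch, n: f"{ch.phys_min:g}", 8)
    header += sig_fields(lambda ch, n: f"{ch.phys_max:g}", 8)
    header += sig_fields(lambda ch, n: str(_DIG_MIN), 8)
    header += sig_fields(lambda ch, n: str(_DIG_MAX), 8)
    header += sig_fields(lambda ch, n: "", 80)            # prefiltering
    header += sig_fields(lambda ch, n: str(n), 8)
    header += sig_fields(lambda ch, n: "", 32)

    digital = []
    for ch, n in zip(channels, spr):
        x = np.asarray(ch.samples, dtype=float)
        if ch.phys_max <= ch.phys_min:
            raise EdfError("physical range must be non-degenerate")
        scale = (_DIG_MAX - _DIG_MIN) / (ch.phys_max - ch.phys_min)
        d = np.rint((x - ch.phys_min) * scale + _DIG_MIN)
        d = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")
        pad = n_records * n - len(d)
        zero = np.rint((0.0 - ch.phys_min) * scale + _DIG_MIN).astype("<i2")
        d = np.concatenate([d, np.full(pad, zero, dtype="<i2")])
        digital.append(d.reshape(n_records, n))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r].tobytes())


def read_edf(path: str | Path) -> list[EdfChannel]:
    """Read all signals from an EDF file at their native rates."""
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise EdfError(f"cannot read {path}: {exc}") from exc
    if len(raw) < 256:
        raise EdfError(f"{path}: truncated EDF header")

    def txt(lo, hi):
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    try:
        n_records = int(txt(236, 244))
        record_s = float(txt(244, 252))
        ns = int(txt(252, 256))
    except ValueError as exc:
        raise EdfError(f"{path}: ill-formed EDF header") from exc
    if ns <= 0 or len(raw) < 256 * (1 + ns):
        raise EdfError(f"{path}: bad signal count or truncated signal headers")

    base = 256
    labels, pmin, pmax, dmin, dmax, spr = [], [], [], [], [], []
    try:
        for i in range(ns):
            labels.append(raw[base + 16 * i: base + 16 * (i + 1)]
                          .decode("ascii", errors="replace").strip())
        o = base + ns * (16 + 80 + 8)   # skip transducer + phys dim
        for i in range(ns):
            pmin.append(float(raw[o + 8 * i: o + 8 * (i + 1)].decode().strip()))
        o += 8 * ns
        for i in range(ns):
            pmax.append(float(raw[o + 8 * i: o + 8 * (i + 1)].decode().strip()))
        o += 8 * ns
        for i in range(ns):
            dmin.append(int(raw[o + 8 * i: o + 8 * (i + 1)].decode().strip()))
        o += 8 * ns
        for i in range(ns):
            dmax.append(int(raw[o + 8 * i: o + 8 * (i + 1)].decode().strip()))
        o += 8 * ns + 80 * ns           # skip prefiltering
        for i in range(ns):
            spr.append(int(raw[o + 8 * i: o + 8 * (i + 1)].decode().strip()))
    except ValueError as exc:
        raise EdfError(f"{path}: ill-formed EDF signal header") from exc

    data_start = 256 * (1 + ns)
    rec_len = sum(spr) * 2
    if n_records < 0:  # -1 means "unknown" in EDF; infer from file size
        n_records = (len(raw) - data_start) // rec_len
    if len(raw) < data_start + n_records * rec_len:
        raise EdfError(f"{path}: file shorter than declared data records")

    out: list[EdfChannel] = []
    body = np.frombuffer(raw, dtype="<i2", offset=data_start,
                         count=n_records * rec_len // 2)
    body = body.reshape(n_records, rec_len // 2)
    col = 0
    for i in range(ns):
        block = body[:, col: col + spr[i]]
        col += spr[i]
        if dmax[i] == dmin[i]:
            raise EdfError(f"{path}: degenerate digital range for signal {i}")
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (block.astype(float) - dmin[i]) * scale + pmin[i]
        out.append(EdfChannel(
            label=labels[i],
            rate=spr[i] / record_s,
            samples=phys.reshape(-1),
            phys_min=pmin[i],
            phys_max=pmax[i],
        ))
    return out
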