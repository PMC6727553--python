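"""Polysomnography signal and hypnogram I/O.

A recording pairs one EEG channel (nominally 200 Hz, 0.1-70 Hz band) with
one EMG channel (nominally 500 Hz); the two are digitized synchronously but
at independent rates, so they are stored and validated as separate sample
streams over a common time axis.  Hypnograms are stage-label sequences at a
fixed epoch length (10 s by default), in either the five-stage alphabet
``W, N1, N2, TS, R`` or the collapsed three-stage alphabet ``W, N, R``.

Supported on-disk formats are EDF (European Data Format, 16-bit) and plain
CSV (one column per channel, exact decimal text).  Reading never resamples:
rates always come from file metadata or the sidecar config.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import _edf

#: Epoch length used throughout (seconds).
DEFAULT_EPOCH_S = 10.0

#: Five-stage alphabet: wake, light NREM, deep NREM, transition sleep, REM.
STAGES_5 = ("W", "N1", "N2", "TS", "R")
#: Three-stage alphabet after merging the NREM family.
STAGES_3 = ("W", "N", "R")


class FormatError(ValueError):
    """Raised for unreadable or ill-formed signal/hypnogram files."""


@dataclass
class IOConfig:
    """Channel selection and CSV-rate configuration.

    ``eeg_pattern``/``emg_pattern`` are case-insensitive regular expressions
    matched against channel labels (EDF) or CSV header names.  CSV files
    carry no rate metadata, so ``csv_eeg_rate``/``csv_emg_rate`` supply it;
    a YAML sidecar (``<file>.yaml``) with the same keys takes precedence.
    """

    eeg_pattern: str = "eeg"
    emg_pattern: str = "emg"
    csv_eeg_rate: float = 200.0
    csv_emg_rate: float = 500.0
    epoch_s: float = DEFAULT_EPOCH_S

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IOConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class Recording:
    """One EEG + one EMG stream with independent sampling rates.

    Samples are in microvolts.  The two channel durations must agree to
    within one epoch; the analyzable duration is the minimum of the two.
    """

    eeg: np.ndarray
    eeg_rate: float
    emg: np.ndarray
    emg_rate: float
    subject_id: str = ""
    start_time_s: float = 0.0
    epoch_s: float = DEFAULT_EPOCH_S

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        for name, rate in (("eeg_rate", self.eeg_rate), ("emg_rate", self.emg_rate)):
            if not np.isfinite(rate) or rate <= 0:
                raise ValueError(f"{name} must be a finite positive number, got {rate}")
        for name, x in (("eeg", self.eeg), ("emg", self.emg)):
            if x.ndim != 1:
                raise ValueError(f"{name} samples must be one-dimensional")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"{name} contains non-finite samples")
        if abs(self.eeg_duration_s - self.emg_duration_s) > self.epoch_s:
            raise ValueError(
                "EEG/EMG duration mismatch exceeds one epoch: "
                f"{self.eeg_duration_s:.2f} s vs {self.emg_duration_s:.2f} s"
            )

    @property
    def eeg_duration_s(self) -> float:
        return len(self.eeg) / self.eeg_rate

    @property
    def emg_duration_s(self) -> float:
        return len(self.emg) / self.emg_rate

    @property
    def duration_s(self) -> float:
        """Common analyzable duration (minimum of the two channels)."""
        return min(self.eeg_duration_s, self.emg_duration_s)


def _detect_alphabet(labels: Sequence[str]) -> tuple[str, ...]:
    toks = set(labels)
    if toks <= set(STAGES_3):
        # "W"/"R"-only hypnograms are valid in either alphabet; treat the
        # collapsed alphabet as the default for ambiguous token sets.
        return STAGES_3 if "N" in toks or not toks <= set(STAGES_5) else STAGES_5
    if toks <= set(STAGES_5):
        return STAGES_5
    raise ValueError(f"labels mix or fall outside the stage alphabets: {sorted(toks)}")


@dataclass
class Hypnogram:
    """Ordered stage labels at fixed epoch length, with optional artifact flags.

    The alphabet (5-stage or 3-stage) is inferred from the labels when not
    given explicitly; label sets like {W, R} that fit both alphabets default
    to 5-stage, so pass ``alphabet=STAGES_3`` for collapsed hypnograms.
    """

    labels: list[str]
    epoch_s: float = DEFAULT_EPOCH_S
    artifact: Optional[list[bool]] = None
    alphabet: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if self.alphabet is None:
            self.alphabet = _detect_alphabet(self.labels)
        else:
            self.alphabet = tuple(self.alphabet)
            if not set(self.labels) <= set(self.alphabet):
                raise ValueError(
                    f"labels {sorted(set(self.labels))} outside declared "
                    f"alphabet {self.alphabet}"
                )
        if self.artifact is not None:
            self.artifact = [bool(a) for a in self.artifact]
            if len(self.artifact) != len(self.labels):
                raise ValueError(
                    f"artifact flags ({len(self.artifact)}) and labels "
                    f"({len(self.labels)}) differ in length"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.epoch_s == other.epoch_s
            and self.artifact == other.artifact
        )


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "edf" if path.suffix.lower() == ".edf" else "csv"


def _match_channel(labels: Sequence[str], pattern: str, kind: str) -> int:
    rx = re.compile(pattern, re.IGNORECASE)
    for i, lab in enumerate(labels):
        if rx.search(lab):
            return i
    raise FormatError(
        f"channel not found: no label matches {kind} pattern {pattern!r}; "
        f"available labels: {list(labels)}"
    )


def read_recording(
    path: str | Path,
    fmt: Optional[str] = None,
    config: Optional[IOConfig] = None,
) -> Recording:
    """Read a Recording from an EDF or CSV file.

    Rates are taken from file metadata (EDF) or the config/sidecar (CSV);
    no resampling is ever performed.  Raises :class:`FormatError` for
    missing channels or unreadable files, and ``ValueError`` when the two
    channel durations differ by more than one epoch.
    """
    path = Path(path)
    config = config or IOConfig()
    sidecar = Path(str(path) + ".yaml")
    if sidecar.exists():
        config = IOConfig.from_yaml(sidecar)
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        try:
            channels = _edf.read_edf(path)
        except _edf.EdfError as exc:
            raise FormatError(str(exc)) from exc
        labels = [c.label for c in channels]
        i_eeg = _match_channel(labels, config.eeg_pattern, "EEG")
        i_emg = _match_channel(labels, config.emg_pattern, "EMG")
        return Recording(
            eeg=channels[i_eeg].samples,
            eeg_rate=channels[i_eeg].rate,
            emg=channels[i_emg].samples,
            emg_rate=channels[i_emg].rate,
            subject_id=path.stem,
            epoch_s=config.epoch_s,
        )
    if fmt == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise FormatError(f"{path}: empty CSV signal file")
        header = [h.strip() for h in rows[0]]
        i_eeg = _match_channel(header, config.eeg_pattern, "EEG")
        i_emg = _match_channel(header, config.emg_pattern, "EMG")
        cols: dict[int, list[float]] = {i_eeg: [], i_emg: []}
        for lineno, row in enumerate(rows[1:], start=2):
            for i in (i_eeg, i_emg):
                if i < len(row) and row[i].strip() != "":
                    try:
                        cols[i].append(float(row[i]))
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: bad sample {row[i]!r}") from exc
        return Recording(
            eeg=np.array(cols[i_eeg]),
            eeg_rate=config.csv_eeg_rate,
            emg=np.array(cols[i_emg]),
            emg_rate=config.csv_emg_rate,
            subject_id=path.stem,
            epoch_s=config.epoch_s,
        )
    raise FormatError(f"unknown recording format {fmt!r}")


#: Default EDF physical ranges (µV); span typical rat EEG/EMG amplitudes
#: with headroom.
EDF_EEG_RANGE = (-1000.0, 1000.0)
EDF_EMG_RANGE = (-500.0, 500.0)


def write_recording(
    recording: Recording,
    path: str | Path,
    fmt: Optional[str] = None,
) -> None:
    """Write a Recording to EDF (16-bit quantized) or CSV (exact text)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        _edf.write_edf(
            path,
            [
                _edf.EdfChannel("EEG", recording.eeg_rate, recording.eeg,
                                *EDF_EEG_RANGE),
                _edf.EdfChannel("EMG", recording.emg_rate, recording.emg,
                                *EDF_EMG_RANGE),
            ],
        )
        return
    if fmt == "csv":
        n = max(len(recording.eeg), len(recording.emg))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["eeg", "emg"])
            for i in range(n):
                writer.writerow([
                    repr(float(recording.eeg[i])) if i < len(recording.eeg) else "",
                    repr(float(recording.emg[i])) if i < len(recording.emg) else "",
                ])
        return
    raise FormatError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# Hypnogram I/O
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, epoch_s: float = DEFAULT_EPOCH_S) -> Hypnogram:
    """Read a hypnogram CSV with columns ``epoch_index,stage[,artifact]``."""
    path = Path(path)
    valid = set(STAGES_5) | set(STAGES_3)
    labels: list[str] = []
    flags: list[bool] = []
    has_flags = False
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and len(row) > 1 and row[1].strip().lower() == "stage":
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected epoch_index,stage")
            tok = row[1].strip()
            if tok not in valid:
                raise FormatError(f"{path}:{lineno}: unknown stage label {tok!r}")
            labels.append(tok)
            if len(row) >= 3 and row[2].strip() != "":
                has_flags = True
                flags.append(row[2].strip() not in ("0", "false", "False"))
            else:
                flags.append(False)
    if not labels:
        raise FormatError(f"{path}: no epochs found")
    return Hypnogram(labels, epoch_s=epoch_s, artifact=flags if has_flags else None)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if hypnogram.artifact is None:
            writer.writerow(["epoch_index", "stage"])
            for i, lab in enumerate(hypnogram.labels):
                writer.writerow([i, lab])
        else:
            writer.writerow(["epoch_index", "stage", "artifact"])
            for i, (lab, a) in enumerate(zip(hypnogram.labels, hypnogram.artifact)):
                writer.writerow([i, lab, int(a)])
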