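"""Spectral and EMG feature extraction on 2-s segments.

Every 10-s epoch is divided into five non-overlapping 2-s segments.  Per
segment, ten features are computed:

* six mean band powers in dB — EEG_lo [0, 0.5), delta [0.5, 5),
  theta [6, 9), alpha [10.5, 15), beta [22, 30), gamma [35, 45) Hz —
  as the mean over the band's 0.5-Hz periodogram bins of
  ``10·log10(power + floor)``;
* three power ratios — EEG_lo, delta and alpha band power divided by
  total [0, 30) Hz power, from raw (not dB) bin powers;
* EMG energy — the mean absolute amplitude of the 10-100 Hz band-passed
  EMG over the same 2-s window.

The periodogram is a plain rectangular-window FFT, one-sided, with DC and
Nyquist bins unhalved, so the bin powers sum to the mean square of the
segment (Parseval).  A 2-s segment gives exactly the 0.5-Hz grid the band
definitions assume, at any sampling rate.  Nothing is demeaned: the DC bin
is the EEG_lo band, which the movement-artifact rules rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Recording

#: additive floor (µV²) inside the log so empty bands stay finite (-120 dB)
DB_FLOOR = 1e-12


class BandDefinition(NamedTuple):
    """Half-open frequency band [lo_hz, hi_hz) on the 0.5-Hz grid."""

    name: str
    lo_hz: float
    hi_hz: float


BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in [
        BandDefinition("eeg_lo", 0.0, 0.5),
        BandDefinition("delta", 0.5, 5.0),
        BandDefinition("theta", 6.0, 9.0),
        BandDefinition("alpha", 10.5, 15.0),
        BandDefinition("beta", 22.0, 30.0),
        BandDefinition("gamma", 35.0, 45.0),
        BandDefinition("total", 0.0, 30.0),
    ]
}

#: the ten per-segment features, in canonical column order
FEATURE_NAMES = [
    "sp_lo", "sp_delta", "sp_theta", "sp_alpha", "sp_beta", "sp_gamma",
    "pr_lo", "pr_delta", "pr_alpha", "emg_energy",
]

_SP_BANDS = {
    "sp_lo": "eeg_lo", "sp_delta": "delta", "sp_theta": "theta",
    "sp_alpha": "alpha", "sp_beta": "beta", "sp_gamma": "gamma",
}
_PR_BANDS = {"pr_lo": "eeg_lo", "pr_delta": "delta", "pr_alpha": "alpha"}


def epoch_count(duration_s: float, epoch_s: float = 10.0) -> int:
    """Number of whole epochs in a recording; the trailing partial epoch is dropped."""
    return int(np.floor(duration_s / epoch_s + 1e-9))


def segment_epochs(
    recording: Recording, epoch_s: float = 10.0, segment_s: float = 2.0
) -> list[list[float]]:
    """Segment start times (s), grouped per epoch.

    Raises ``ValueError`` for a recording shorter than one epoch or when
    ``epoch_s`` is not an integer multiple of ``segment_s``.
    """
    per_epoch = epoch_s / segment_s
    if abs(per_epoch - round(per_epoch)) > 1e-9:
        raise ValueError("epoch_s must be an integer multiple of segment_s")
    n_epochs = epoch_count(recording.duration_s, epoch_s)
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration_s:.2f} s is shorter than one "
            f"{epoch_s:g}-s epoch"
        )
    per_epoch = int(round(per_epoch))
    return [
        [e * epoch_s + s * segment_s for s in range(per_epoch)]
        for e in range(n_epochs)
    ]


def periodogram(segment: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram of a 2-s segment.

    Returns ``(freqs, power)`` with bins on the 0.5-Hz grid.  Bin powers
    are in µV² and satisfy ``sum(power) == mean(segment**2)``.
    """
    x = np.asarray(segment, dtype=float)
    n = int(round(rate * 2.0))
    if len(x) != n:
        raise ValueError(f"expected a 2-s segment of {n} samples, got {len(x)}")
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not mirrored
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, power


def _band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.lo_hz - 1e-9) & (freqs < band.hi_hz - 1e-9)
    if not mask.any():
        raise ValueError(f"band {band.name} [{band.lo_hz},{band.hi_hz}) has no "
                         "bins on this frequency grid")
    return mask


def band_power_db(power: np.ndarray, freqs: np.ndarray, band: BandDefinition) -> float:
    """Mean over the band's bins of 10·log10(bin power + floor), in dB."""
    mask = _band_mask(freqs, band)
    return float(np.mean(10.0 * np.log10(power[mask] + DB_FLOOR)))


def power_ratio(
    power: np.ndarray,
    freqs: np.ndarray,
    band: BandDefinition,
    total: BandDefinition = BANDS["total"],
) -> float:
    """Raw band power divided by raw total-band power; 0 when total is 0."""
    band_sum = float(np.sum(power[_band_mask(freqs, band)]))
    total_sum = float(np.sum(power[_band_mask(freqs, total)]))
    if total_sum == 0.0:
        return 0.0
    return band_sum / total_sum


def emg_bandpass(
    emg: np.ndarray, rate: float, lo_hz: float = 10.0, hi_hz: float = 100.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass over the whole EMG channel.

    Applied forward-backward so segment alignment is preserved.  Requires
    ``rate > 2*hi_hz`` (Nyquist above the passband).
    """
    if rate <= 2 * hi_hz:
        raise ValueError(
            f"EMG rate {rate} Hz too low for a {lo_hz}-{hi_hz} Hz band-pass"
        )
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(emg, dtype=float))


def emg_energy(filtered_segment: np.ndarray) -> float:
    """Mean absolute amplitude (µV) of a band-passed EMG segment."""
    return float(np.mean(np.abs(filtered_segment)))


@dataclass
class FeatureMatrix:
    """Per-segment feature table with epoch grouping metadata.

    ``data`` has one row per 2-s segment with columns ``epoch``,
    ``segment`` and the ten features of :data:`FEATURE_NAMES`.
    """

    data: pd.DataFrame
    epoch_s: float = 10.0
    segment_s: float = 2.0
    eeg_rate: float = 200.0
    emg_rate: float = 500.0

    @property
    def n_epochs(self) -> int:
        return int(self.data["epoch"].nunique())

    @property
    def segments_per_epoch(self) -> int:
        return int(round(self.epoch_s / self.segment_s))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def extract_features(
    recording: Recording, epoch_s: float = 10.0, segment_s: float = 2.0
) -> FeatureMatrix:
    """Compute the ten features for every 2-s segment of a recording.

    EEG features come from the EEG channel and EMG energy from the
    band-passed EMG; segment k of both channels covers the same
    ``[k·segment_s, (k+1)·segment_s)`` window regardless of rate.
    """
    boundaries = segment_epochs(recording, epoch_s, segment_s)
    emg_filtered = emg_bandpass(recording.emg, recording.emg_rate)
    n_eeg = int(round(recording.eeg_rate * segment_s))
    n_emg = int(round(recording.emg_rate * segment_s))

    rows = []
    for e, starts in enumerate(boundaries):
        for s, t0 in enumerate(starts):
            i_eeg = int(round(t0 * recording.eeg_rate))
            i_emg = int(round(t0 * recording.emg_rate))
            freqs, power = periodogram(recording.eeg[i_eeg:i_eeg + n_eeg],
                                       recording.eeg_rate)
            row: dict[str, float] = {"epoch": e, "segment": s}
            for feat, band in _SP_BANDS.items():
                row[feat] = band_power_db(power, freqs, BANDS[band])
            for feat, band in _PR_BANDS.items():
                row[feat] = power_ratio(power, freqs, BANDS[band])
            row["emg_energy"] = emg_energy(emg_filtered[i_emg:i_emg + n_emg])
            rows.append(row)

    data = pd.DataFrame(rows, columns=["epoch", "segment"] + FEATURE_NAMES)
    data[["epoch", "segment"]] = data[["epoch", "segment"]].astype(int)
    return FeatureMatrix(
        data=data, epoch_s=epoch_s, segment_s=segment_s,
        eeg_rate=recording.eeg_rate, emg_rate=recording.emg_rate,
    )
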