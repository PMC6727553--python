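"""Stage indexes computed from normalized features.

The four primary indexes contrast the stage signatures via ratios of the
normalized features (EMG = normalized EMG energy; delta/theta/alpha/beta/
gamma/EEG_lo = normalized band powers):

* ``Index_W = EMG · gamma / delta`` — muscle tone and fast activity over
  slow waves: high in wake;
* ``Index_N = delta · alpha / gamma²`` — slow waves and spindles over fast
  activity: high in NREM;
* ``Index_R = theta³ / (delta · alpha · EMG)`` — regular theta with atonia:
  high in REM;
* ``Index_A = ((2·EEG_lo) + beta) · gamma / ΣEEG`` with
  ``ΣEEG = delta + theta + alpha + beta + gamma`` — broadband/baseline
  surges: high during movement artifacts.

The four secondary indexes refine within a condition: ``Index_1`` is
identically ``Index_W``; ``Index_2 = alpha·delta/theta`` (NREM1 signature);
``Index_3 = theta·gamma/delta`` and ``Index_4 = delta/theta`` separate
transition sleep from NREM proper.

Indexes are computed per 2-s segment and averaged over the five segments
of each epoch; denominators are floored at ``EPS`` (numerators never are),
so every index is finite and non-negative.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: floor applied to index denominators only; clipped normalized features
#: can be exactly 0
EPS = 1e-6

SEGMENT_INDEX_COLUMNS = [
    "index_w", "index_n", "index_r", "index_a",
    "index_1", "index_2", "index_3", "index_4",
]


def _den(x):
    return np.maximum(np.asarray(x, dtype=float), EPS)


def primary_indexes(f: Mapping[str, float]) -> tuple[float, float, float, float]:
    """(Index_W, Index_N, Index_R, Index_A) for one normalized segment.

    ``f`` maps feature names (``sp_delta`` ... ``emg_energy``) to values
    in [0, 1].
    """
    emg, lo = f["emg_energy"], f["sp_lo"]
    d, t, a = f["sp_delta"], f["sp_theta"], f["sp_alpha"]
    b, g = f["sp_beta"], f["sp_gamma"]
    sum_eeg = d + t + a + b + g
    return (
        float(emg * g / _den(d)),
        float(d * a / _den(g) ** 2),
        float(t**3 / (_den(d) * _den(a) * _den(emg))),
        float(((2.0 * lo) + b) * g / _den(sum_eeg)),
    )


def secondary_indexes(f: Mapping[str, float]) -> tuple[float, float, float, float]:
    """(Index_1, Index_2, Index_3, Index_4) for one normalized segment."""
    emg = f["emg_energy"]
    d, t, a, g = f["sp_delta"], f["sp_theta"], f["sp_alpha"], f["sp_gamma"]
    return (
        float(emg * g / _den(d)),
        float(a * d / _den(t)),
        float(t * g / _den(d)),
        float(d / _den(t)),
    )


def segment_indexes(norm: pd.DataFrame) -> pd.DataFrame:
    """All eight indexes per segment from a normalized feature table.

    ``norm`` is the output of :func:`ratsleep.calibration.normalize_features`
    (columns ``epoch``, ``segment`` and the ten features).
    """
    emg = norm["emg_energy"].to_numpy()
    lo = norm["sp_lo"].to_numpy()
    d = norm["sp_delta"].to_numpy()
    t = norm["sp_theta"].to_numpy()
    a = norm["sp_alpha"].to_numpy()
    b = norm["sp_beta"].to_numpy()
    g = norm["sp_gamma"].to_numpy()
    sum_eeg = d + t + a + b + g

    out = pd.DataFrame({
        "epoch": norm["epoch"].to_numpy(),
        "segment": norm["segment"].to_numpy(),
        "index_w": emg * g / _den(d),
        "index_n": d * a / _den(g) ** 2,
        "index_r": t**3 / (_den(d) * _den(a) * _den(emg)),
        "index_a": ((2.0 * lo) + b) * g / _den(sum_eeg),
        "index_2": a * d / _den(t),
        "index_3": t * g / _den(d),
        "index_4": d / _den(t),
    })
    out["index_1"] = out["index_w"]  # identical by definition
    return out[["epoch", "segment"] + SEGMENT_INDEX_COLUMNS]


def aggregate_epoch(segment_sets: pd.DataFrame) -> pd.Series:
    """Epoch-level index set: the mean of exactly five segment index sets.

    Returns the per-index means plus ``snra``, the sum
    ``Index_N + Index_R + Index_A`` of the epoch means.
    """
    if len(segment_sets) != 5:
        raise ValueError(f"an epoch has 5 segments, got {len(segment_sets)}")
    means = segment_sets[SEGMENT_INDEX_COLUMNS].mean()
    means["snra"] = means["index_n"] + means["index_r"] + means["index_a"]
    return means


def epoch_indexes(seg: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch mean indexes (+ ``snra``) from a per-segment index table."""
    counts = seg.groupby("epoch").size()
    if not (counts == 5).all():
        bad = counts[counts != 5].index.tolist()
        raise ValueError(f"epochs without exactly 5 segments: {bad}")
    means = seg.groupby("epoch")[SEGMENT_INDEX_COLUMNS].mean()
    means["snra"] = means["index_n"] + means["index_r"] + means["index_a"]
    return means.reset_index()


def write_indexes(seg: pd.DataFrame, path: str | Path) -> None:
    """Export per-segment indexes as CSV for audit/debug."""
    seg.to_csv(path, index=False)
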