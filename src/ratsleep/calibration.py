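"""Per-recording feature normalization and node-design utilities.

Normalization rescales each feature so that the mean of its 10% smallest
values maps to 0 and the mean of its 10% largest values maps to 1, with
clipping to [0, 1].  Computed per recording over all of its 2-s segments,
this removes between-subject amplitude differences before any index or
threshold is applied.

Two design-time utilities accompany it: the distribution distance, a
separability score between a feature's distributions under two stages, and
the threshold formula that places a cut midway between the shrunk extreme
deciles.  Both are reported for inspection; the shipped decision tree uses
fixed features and constants and is never re-learned.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureMatrix


class NormalizationBounds(NamedTuple):
    """Extreme-decile anchors for one feature of one recording."""

    min_val: float
    max_val: float
    feature: str = ""


class DistributionStats(NamedTuple):
    """Mean and standard deviation of a feature under one stage."""

    mean: float
    sd: float


def _decile_count(n: int, fraction: float) -> int:
    # "10%" with no stated rounding rule: ceil, at least one value
    return max(1, math.ceil(fraction * n))


def extreme_decile_bounds(
    values: np.ndarray, fraction: float = 0.1, feature: str = ""
) -> NormalizationBounds:
    """Means of the ``fraction`` smallest and largest values.

    With n values, each decile holds ``ceil(fraction*n)`` (at least 1)
    values, so e.g. 1..100 gives bounds (5.5, 95.5).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute bounds of an empty feature series")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature series contains non-finite values")
    k = _decile_count(x.size, fraction)
    xs = np.sort(x)
    return NormalizationBounds(
        min_val=float(np.mean(xs[:k])),
        max_val=float(np.mean(xs[-k:])),
        feature=feature,
    )


def normalize(values: np.ndarray, bounds: NormalizationBounds) -> np.ndarray:
    """Map values through the bounds to [0, 1], clipping outside.

    Degenerate bounds (max == min, a constant feature) map everything to
    0.5 so downstream index denominators stay defined without biasing any
    stage.
    """
    x = np.asarray(values, dtype=float)
    span = bounds.max_val - bounds.min_val
    if span <= 0:
        return np.full_like(x, 0.5)
    return np.clip((x - bounds.min_val) / span, 0.0, 1.0)


def distribution_distance(a: DistributionStats, b: DistributionStats) -> float:
    """Separability of two stage-conditional feature distributions, in [0, 1].

    ``1 - (sd_a + sd_b) / (2|mean_a - mean_b|)`` when the spreads fit inside
    twice the mean gap, else 0 (overlapping distributions).  Symmetric; the
    degenerate case of identical point masses is defined as 0.
    """
    gap = 2.0 * abs(a.mean - b.mean)
    spread = a.sd + b.sd
    if gap == 0.0 or spread > gap:
        return 0.0
    return 1.0 - spread / gap


def feature_threshold(values: np.ndarray, fraction: float = 0.1) -> float:
    """Cut point between the shrunk extreme deciles of a feature.

    ``0.5 * [(mean(10% max) - 0.5*sd(10% max)) + (mean(10% min) + 0.5*sd(10% min))]``
    with sample (n-1) standard deviations; a single-value decile has sd 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute a threshold from an empty series")
    k = _decile_count(x.size, fraction)
    xs = np.sort(x)
    lo, hi = xs[:k], xs[-k:]
    sd_lo = float(np.std(lo, ddof=1)) if k > 1 else 0.0
    sd_hi = float(np.std(hi, ddof=1)) if k > 1 else 0.0
    return 0.5 * ((float(np.mean(hi)) - 0.5 * sd_hi)
                  + (float(np.mean(lo)) + 0.5 * sd_lo))


# ---------------------------------------------------------------------------
# Feature-matrix normalization
# ---------------------------------------------------------------------------

def compute_bounds(fm: FeatureMatrix) -> dict[str, NormalizationBounds]:
    """Extreme-decile bounds for each of the ten features over all segments."""
    return {
        name: extreme_decile_bounds(fm.data[name].to_numpy(), feature=name)
        for name in FEATURE_NAMES
    }


def normalize_features(
    fm: FeatureMatrix,
    bounds: Optional[Mapping[str, NormalizationBounds]] = None,
) -> tuple[pd.DataFrame, dict[str, NormalizationBounds]]:
    """Normalized copy of the feature table plus the bounds used.

    Bounds default to this recording's own extreme deciles; pass stored
    bounds to re-score a recording reproducibly (e.g. streaming use).
    """
    use = dict(bounds) if bounds is not None else compute_bounds(fm)
    out = fm.data.copy()
    for name in FEATURE_NAMES:
        out[name] = normalize(fm.data[name].to_numpy(), use[name])
    return out, use


def write_bounds(bounds: Mapping[str, NormalizationBounds], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature", "min_val", "max_val"])
        for name, b in bounds.items():
            writer.writerow([name, repr(b.min_val), repr(b.max_val)])


def read_bounds(path: str | Path) -> dict[str, NormalizationBounds]:
    out: dict[str, NormalizationBounds] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if not row:
                continue
            out[row[0]] = NormalizationBounds(
                min_val=float(row[1]), max_val=float(row[2]), feature=row[0]
            )
    return out
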