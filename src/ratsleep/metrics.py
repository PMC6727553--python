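"""Agreement statistics between hypnograms.

A confusion matrix (rows = expert-consensus reference, columns = automatic
staging) is the basis for everything: overall agreement (trace/total),
Cohen's kappa, and per-stage one-vs-rest sensitivity, specificity, PPV and
NPV.  Kappa is interpreted on the Landis & Koch bands (poor < 0,
slight ≤ 0.20, fair ≤ 0.40, moderate ≤ 0.60, substantial ≤ 0.80,
excellent > 0.80).

One convention needs care: published validation tables for this scorer
compute SE/SP treating the *automatic column totals* as the reference
condition (wake SE = wake diagonal / wake column total), with the
row-based value appearing as PPV.  :func:`stage_metrics` therefore takes
an explicit ``reference_axis``; ``"columns"`` reproduces those tables,
``"rows"`` is the conventional default for new analyses.

Only epochs both human scorers labeled identically (consensus epochs)
enter validation; :func:`consensus_epochs` builds that mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Hypnogram

#: marker for statistics whose denominator is zero — never reported as 0 or 100
UNDEFINED = float("nan")


def round_display(x: float, nd: int = 2) -> float:
    """Round half away from zero to ``nd`` decimals (table display convention)."""
    q = Decimal(1).scaleb(-nd)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Square label-indexed count matrix (rows = reference, columns = test)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} labels"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))

    def collapse(self, mapping: dict[str, str],
                 order: Sequence[str]) -> "ConfusionMatrix":
        """Merge rows and columns under a label mapping (e.g. 5→3 stages)."""
        order = tuple(order)
        k = len(order)
        out = np.zeros((k, k), dtype=np.int64)
        pos = {lab: i for i, lab in enumerate(order)}
        for i, ri in enumerate(self.labels):
            for j, cj in enumerate(self.labels):
                out[pos[mapping[ri]], pos[mapping[cj]]] += self.counts[i, j]
        return ConfusionMatrix(order, out)


COLLAPSE_5_TO_3 = {"W": "W", "N1": "N", "N2": "N", "TS": "N", "R": "R"}


def consensus_epochs(h1: Hypnogram, h2: Hypnogram) -> np.ndarray:
    """Boolean mask of epochs the two scorers labeled identically."""
    if len(h1) != len(h2):
        raise ValueError(f"hypnogram lengths differ: {len(h1)} vs {len(h2)}")
    if h1.alphabet != h2.alphabet:
        raise ValueError("hypnograms use different stage alphabets")
    return np.array([a == b for a, b in zip(h1.labels, h2.labels)])


def confusion(
    reference: Hypnogram,
    test: Hypnogram,
    mask: Optional[np.ndarray] = None,
) -> ConfusionMatrix:
    """Count epochs per (reference label, test label), optionally masked."""
    if len(reference) != len(test):
        raise ValueError(
            f"hypnogram lengths differ: {len(reference)} vs {len(test)}"
        )
    if reference.alphabet != test.alphabet:
        raise ValueError("hypnograms use different stage alphabets")
    labels = tuple(reference.alphabet)
    pos = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    if mask is None:
        mask = np.ones(len(reference), dtype=bool)
    for keep, r, t in zip(mask, reference.labels, test.labels):
        if keep:
            counts[pos[r], pos[t]] += 1
    return ConfusionMatrix(labels, counts)


def overall_agreement(cm: ConfusionMatrix) -> float:
    """100 · trace / total, in percent."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement κ = (Pr(a) − Pr(e)) / (1 − Pr(e)).

    Pr(a) is the observed agreement (trace/total) and Pr(e) the chance
    agreement from the row/column margins.  Returns the undefined marker
    for the degenerate single-category case Pr(e) = 1.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    n = float(cm.total)
    pr_a = float(np.trace(cm.counts)) / n
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    pr_e = float(np.dot(rows, cols)) / n**2
    if pr_e >= 1.0:
        return UNDEFINED
    return (pr_a - pr_e) / (1.0 - pr_e)


def stage_metrics(cm: ConfusionMatrix, reference_axis: str = "rows") -> pd.DataFrame:
    """One-vs-rest SE/SP/PPV/NPV per stage, as percentages.

    ``reference_axis`` selects which margin defines the true condition:
    ``"rows"`` (conventional) or ``"columns"`` (reproduces the published
    validation tables for this scorer).  Zero-denominator statistics are
    NaN, never 0 or 100.
    """
    if reference_axis not in ("rows", "columns"):
        raise ValueError("reference_axis must be 'rows' or 'columns'")
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    c = cm.counts.astype(float)
    row_tot = c.sum(axis=1)
    col_tot = c.sum(axis=0)
    total = c.sum()
    rows = []
    for i, lab in enumerate(cm.labels):
        tp = c[i, i]
        if reference_axis == "rows":
            fn = row_tot[i] - tp
            fp = col_tot[i] - tp
        else:
            fn = col_tot[i] - tp
            fp = row_tot[i] - tp
        tn = total - tp - fn - fp

        def pct(num, den):
            return 100.0 * num / den if den > 0 else UNDEFINED

        rows.append({
            "stage": lab,
            "se": pct(tp, tp + fn),
            "sp": pct(tn, tn + fp),
            "ppv": pct(tp, tp + fp),
            "npv": pct(tn, tn + fn),
        })
    return pd.DataFrame(rows).set_index("stage")


_KAPPA_BANDS = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
]


def kappa_band(kappa: float) -> str:
    """Landis & Koch interpretation of a kappa value.

    Values in the unprinted gaps between bands (e.g. 0.205) are assigned
    to the band containing their 2-decimal rounding.
    """
    if not np.isfinite(kappa):
        raise ValueError("kappa must be finite")
    r = round_display(kappa, 2)
    if r < 0.0:
        return "poor"
    for hi, name in _KAPPA_BANDS:
        if r <= hi:
            return name
    return "excellent"


def subject_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n−1) standard deviation of per-subject statistics."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty per-subject list")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else UNDEFINED
    return mean, sd


def summarize_hypnogram(
    hyp: Hypnogram,
    light_onset_s: float,
    light_duration_s: float = 12 * 3600.0,
    start_time_s: float = 0.0,
) -> pd.DataFrame:
    """Hours spent per stage in the light and dark periods.

    Epoch i is assigned to the period containing its start time; the light
    period is ``[light_onset_s, light_onset_s + light_duration_s)`` of each
    24-h day, with ``start_time_s`` the clock time of the first epoch.
    """
    day = 24 * 3600.0
    hours: dict[str, dict[str, float]] = {
        lab: {"light": 0.0, "dark": 0.0} for lab in hyp.alphabet
    }
    for i, lab in enumerate(hyp.labels):
        t = (start_time_s + i * hyp.epoch_s - light_onset_s) % day
        period = "light" if t < light_duration_s else "dark"
        hours[lab][period] += hyp.epoch_s / 3600.0
    return pd.DataFrame(hours).T[["light", "dark"]]


def agreement_report(
    cm: ConfusionMatrix, reference_axis: str = "rows"
) -> dict[str, object]:
    """Confusion matrix, per-stage metrics, agreement, κ and its band."""
    kappa = cohens_kappa(cm)
    return {
        "confusion": cm.to_frame(),
        "stage_metrics": stage_metrics(cm, reference_axis),
        "overall_agreement_pct": overall_agreement(cm),
        "kappa": kappa,
        "kappa_band": kappa_band(kappa) if np.isfinite(kappa) else "undefined",
    }
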