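"""Bundled reference benchmark tables.

These CSVs transcribe the published validation of this rule-based scorer
against the consensus of two human experts on 20 rats / 168,656 epochs:
the 5-stage and 3-stage confusion matrices (rows = expert consensus,
columns = automatic staging) and the per-subject agreement/kappa table.
They serve as ground truth for the metric arithmetic — the recordings
themselves are not public.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..metrics import ConfusionMatrix


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _confusion(name: str) -> ConfusionMatrix:
    df = _read(name).set_index("stage")
    return ConfusionMatrix(tuple(df.index), np.asarray(df.to_numpy(), dtype=np.int64))


def reference_confusion_5stage() -> ConfusionMatrix:
    """20-rat 5-stage validation confusion matrix (168,656 consensus epochs)."""
    return _confusion("reference_confusion_5stage.csv")


def reference_confusion_3stage() -> ConfusionMatrix:
    """The same validation collapsed to the 3-stage alphabet."""
    return _confusion("reference_confusion_3stage.csv")


def reference_subject_agreement() -> pd.DataFrame:
    """Per-subject agreement (%) and kappa for the 5- and 3-stage analyses."""
    return _read("reference_subject_agreement.csv")
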