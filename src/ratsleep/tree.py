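"""Two-part, seven-testing-point hierarchical decision tree.

Part 1 assigns every 10-s epoch to one of three conditions from the
epoch-mean primary indexes: an artifact check (testing point 1) sends
epochs whose ``Index_A / (Index_N + Index_R + Index_A)`` ratio exceeds 0.9
to wake, and the rest go to the condition (W, N or R) whose index is
largest.

Part 2 refines each condition into the five stages using per-segment
values.  The band-power-ratio tests use the raw power ratios — the 0.5
delta-ratio cut is the literal "slow waves occupy more than half the
epoch" criterion — while the index-versus-index tests use the indexes
computed from normalized features:

* condition W:  (2) EEG_lo ratio > 0.5 in ≥ 1 segment → WAKE;
                (3) Index_1 > Index_2 in all 5 segments → WAKE; else NREM1.
* condition N:  (4) EEG_lo ratio > 0.5 in ≥ 2 segments → WAKE;
                (5) Index_3 > Index_4 in ≥ 3 segments → TS;
                (6) delta ratio > 0.5 in ≥ 3 segments → NREM2; else NREM1.
* condition R:  (7) alpha ratio > 0.3 in ≥ 1 segment → TS; else REM.

All comparisons are strict, so boundary values fall to the "else" branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, features, indexes
from .io import STAGES_3, Hypnogram, Recording


@dataclass
class TreeConfig:
    """Thresholds and segment counts of the seven testing points."""

    artifact_ratio_threshold: float = 0.9
    lowband_pr_threshold: float = 0.5
    delta_pr_threshold: float = 0.5
    alpha_pr_threshold: float = 0.3
    lowband_wakeW_min_segments: int = 1
    lowband_wakeN_min_segments: int = 2
    ts_min_segments: int = 3
    nrem2_min_segments: int = 3
    #: order in which exact ties between epoch-mean indexes are resolved
    tie_priority: tuple[str, ...] = ("W", "N", "R")

    def __post_init__(self) -> None:
        for name in ("artifact_ratio_threshold", "lowband_pr_threshold",
                     "delta_pr_threshold", "alpha_pr_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("lowband_wakeW_min_segments", "lowband_wakeN_min_segments",
                     "ts_min_segments", "nrem2_min_segments"):
            v = getattr(self, name)
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"{name} must be in 1..5, got {v}")
        if sorted(self.tie_priority) != ["N", "R", "W"]:
            raise ValueError("tie_priority must order exactly W, N, R")


@dataclass
class StageDecision:
    """Outcome of the tree for one epoch, with the fired testing points."""

    stage: str
    condition: str
    artifact: bool
    testing_points: list[int] = field(default_factory=list)


def detect_artifact(mean_a: float, snra: float, cfg: TreeConfig) -> bool:
    """Testing point 1: Index_A / ΣNRA above threshold flags an artifact."""
    ratio = mean_a / max(snra, indexes.EPS)
    return ratio > cfg.artifact_ratio_threshold


def classify_condition(
    mean_w: float, mean_n: float, mean_r: float, cfg: TreeConfig
) -> str:
    """Argmax of the epoch-mean primary indexes; exact ties by priority."""
    vals = {"W": mean_w, "N": mean_n, "R": mean_r}
    best = max(vals.values())
    for cond in cfg.tie_priority:
        if vals[cond] == best:
            return cond
    raise AssertionError("unreachable")


def refine_stage_W(
    pr_lo: np.ndarray, index_1: np.ndarray, index_2: np.ndarray, cfg: TreeConfig
) -> tuple[str, list[int]]:
    """Testing points 2-3 (condition W): wake vs NREM1."""
    if np.sum(pr_lo > cfg.lowband_pr_threshold) >= cfg.lowband_wakeW_min_segments:
        return "W", [2]
    if np.all(index_1 > index_2):
        return "W", [3]
    return "N1", [3]


def refine_stage_N(
    pr_lo: np.ndarray,
    pr_delta: np.ndarray,
    index_3: np.ndarray,
    index_4: np.ndarray,
    cfg: TreeConfig,
) -> tuple[str, list[int]]:
    """Testing points 4-6 (condition N): wake vs TS vs NREM2 vs NREM1."""
    if np.sum(pr_lo > cfg.lowband_pr_threshold) >= cfg.lowband_wakeN_min_segments:
        return "W", [4]
    if np.sum(index_3 > index_4) >= cfg.ts_min_segments:
        return "TS", [4, 5]
    if np.sum(pr_delta > cfg.delta_pr_threshold) >= cfg.nrem2_min_segments:
        return "N2", [4, 5, 6]
    return "N1", [4, 5, 6]


def refine_stage_R(pr_alpha: np.ndarray, cfg: TreeConfig) -> tuple[str, list[int]]:
    """Testing point 7 (condition R): TS vs REM."""
    if np.sum(pr_alpha > cfg.alpha_pr_threshold) >= 1:
        return "TS", [7]
    return "R", [7]


def classify_epoch(
    epoch_means: pd.Series,
    seg_idx: pd.DataFrame,
    seg_raw: pd.DataFrame,
    cfg: TreeConfig,
) -> StageDecision:
    """Run both tree parts for one epoch.

    ``epoch_means`` carries the epoch-mean indexes (+ ``snra``);
    ``seg_idx`` the five per-segment index sets; ``seg_raw`` the five raw
    feature rows (for the band-power-ratio tests).
    """
    if detect_artifact(epoch_means["index_a"], epoch_means["snra"], cfg):
        return StageDecision(stage="W", condition="W", artifact=True,
                             testing_points=[1])
    cond = classify_condition(
        epoch_means["index_w"], epoch_means["index_n"], epoch_means["index_r"], cfg
    )
    pr_lo = seg_raw["pr_lo"].to_numpy()
    pr_delta = seg_raw["pr_delta"].to_numpy()
    pr_alpha = seg_raw["pr_alpha"].to_numpy()
    if cond == "W":
        stage, pts = refine_stage_W(
            pr_lo, seg_idx["index_1"].to_numpy(), seg_idx["index_2"].to_numpy(), cfg
        )
    elif cond == "N":
        stage, pts = refine_stage_N(
            pr_lo, pr_delta,
            seg_idx["index_3"].to_numpy(), seg_idx["index_4"].to_numpy(), cfg,
        )
    else:
        stage, pts = refine_stage_R(pr_alpha, cfg)
    return StageDecision(stage=stage, condition=cond, artifact=False,
                         testing_points=[1] + pts)


def score_features(
    fm: features.FeatureMatrix,
    cfg: TreeConfig | None = None,
    bounds=None,
) -> tuple[Hypnogram, pd.DataFrame]:
    """Score an extracted feature matrix: 5-stage hypnogram plus trace.

    The trace has one row per epoch with the condition, stage, artifact
    flag and fired testing points.
    """
    cfg = cfg or TreeConfig()
    norm, _ = calibration.normalize_features(fm, bounds)
    seg = indexes.segment_indexes(norm)
    ep = indexes.epoch_indexes(seg).set_index("epoch")

    seg_groups = dict(tuple(seg.groupby("epoch")))
    raw_groups = dict(tuple(fm.data.groupby("epoch")))
    labels: list[str] = []
    artifacts: list[bool] = []
    trace_rows = []
    for e, means in ep.iterrows():
        decision = classify_epoch(means, seg_groups[e], raw_groups[e], cfg)
        labels.append(decision.stage)
        artifacts.append(decision.artifact)
        trace_rows.append({
            "epoch": int(e),
            "condition": decision.condition,
            "stage": decision.stage,
            "artifact": decision.artifact,
            "testing_points": "+".join(map(str, decision.testing_points)),
        })
    hyp = Hypnogram(labels, epoch_s=fm.epoch_s, artifact=artifacts)
    return hyp, pd.DataFrame(trace_rows)


def score_recording(
    recording: Recording, cfg: TreeConfig | None = None, bounds=None
) -> tuple[Hypnogram, pd.DataFrame]:
    """End-to-end scoring: features → normalization → indexes → tree."""
    fm = features.extract_features(recording)
    return score_features(fm, cfg, bounds)


_COLLAPSE = {"W": "W", "N1": "N", "N2": "N", "TS": "N", "R": "R"}


def collapse_to_3stage(hyp5: Hypnogram) -> Hypnogram:
    """Merge NREM1, NREM2 and TS into a single NREM label."""
    if set(hyp5.labels) - set(_COLLAPSE):
        raise ValueError("collapse_to_3stage expects a 5-stage hypnogram")
    return Hypnogram(
        [_COLLAPSE[lab] for lab in hyp5.labels],
        epoch_s=hyp5.epoch_s,
        artifact=list(hyp5.artifact) if hyp5.artifact is not None else None,
        alphabet=STAGES_3,
    )
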