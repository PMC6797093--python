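"""Counting metrics: match predicted plant points to ground truth.

The unit of evaluation is the plant point, not the bounding box. Predicted
points are paired one-to-one with ground-truth plant positions within a
match radius (default: the merge threshold of the reference altitude), and
the counts feed the three metrics

    precision        = correct / all detected
    recall           = correct / ground truth
    overall accuracy = (precision + recall) / 2

reported to three decimals (rounded half away from zero) but stored
unrounded.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from ._util import round_half_away

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthSet",
    "MatchSpec",
    "CountMetrics",
    "MatchResult",
    "match_points",
    "compute_metrics",
    "load_ground_truth",
    "save_ground_truth",
]


@dataclasses.dataclass
class GroundTruthSet:
    """True plant positions (px) in reference-mosaic coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = pts

    @property
    def count(self) -> int:
        return len(self.points)


@dataclasses.dataclass(frozen=True)
class MatchSpec:
    """Geometric matching rule: one-to-one pairing within ``match_radius_px``."""

    match_radius_px: float = 30.0
    method: str = "greedy"  # or "optimal" (max-cardinality assignment)

    def __post_init__(self) -> None:
        if self.match_radius_px <= 0:
            raise ValueError("match_radius_px must be positive")
        if self.method not in ("greedy", "optimal"):
            raise ValueError("method must be 'greedy' or 'optimal'")


@dataclasses.dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple  # (pred_index, gt_index) pairs


@dataclasses.dataclass(frozen=True)
class CountMetrics:
    """Correct/detected/ground-truth counts and the derived rates."""

    correct: int
    all_detected: int
    gt_count: int
    precision: float
    recall: float
    overall_accuracy: float

    def rounded(self, ndigits: int = 3) -> tuple[float, float, float]:
        """(recall, precision, overall) rounded half away from zero."""
        f = 10.0**ndigits
        return tuple(
            float(round_half_away(v * f) / f)
            for v in (self.recall, self.precision, self.overall_accuracy)
        )

    def __str__(self) -> str:
        r, p, o = self.rounded()
        return (
            f"correct={self.correct} detected={self.all_detected} "
            f"gt={self.gt_count} recall={r:.3f} precision={p:.3f} overall={o:.3f}"
        )


def _pairs_within(pred: np.ndarray, gt: np.ndarray, radius: float):
    """(distance, pred_i, gt_j) for all pairs within radius, sorted."""
    tree = cKDTree(gt)
    out = []
    for i, neigh in enumerate(tree.query_ball_point(pred, r=radius)):
        for j in neigh:
            out.append((float(np.hypot(*(pred[i] - gt[j]))), i, j))
    out.sort()
    return out


def match_points(
    pred: Sequence, gt: GroundTruthSet, spec: MatchSpec = MatchSpec()
) -> MatchResult:
    """One-to-one pairing of predictions with ground-truth plants.

    ``greedy`` (default, deterministic and auditable): admissible pairs
    (distance <= radius) are taken in ascending distance order, each point
    used at most once. ``optimal`` solves the assignment problem for
    maximum pair count / minimum total distance. TP = pairs, FP = unmatched
    predictions, FN = unmatched ground truth.

    ``pred`` may contain plant points or plain ``(x, y)`` pairs.
    """
    pred_a = np.array(
        [(p.x, p.y) if hasattr(p, "x") else (p[0], p[1]) for p in pred], dtype=float
    ).reshape(-1, 2)
    gt_a = gt.points
    if len(pred_a) == 0 or len(gt_a) == 0:
        return MatchResult(0, len(pred_a), len(gt_a), ())

    if spec.method == "greedy":
        used_p: set[int] = set()
        used_g: set[int] = set()
        pairs = []
        for _, i, j in _pairs_within(pred_a, gt_a, spec.match_radius_px):
            if i in used_p or j in used_g:
                continue
            used_p.add(i)
            used_g.add(j)
            pairs.append((i, j))
    else:
        # max-cardinality min-cost assignment: forbidden pairs get a cost
        # larger than any chain of admissible ones can offset
        d = np.linalg.norm(pred_a[:, None, :] - gt_a[None, :, :], axis=2)
        big = spec.match_radius_px * (len(pred_a) + len(gt_a) + 1) * 1000.0
        cost = np.where(d <= spec.match_radius_px, d, big)
        ri, cj = linear_sum_assignment(cost)
        pairs = [(int(i), int(j)) for i, j in zip(ri, cj) if d[i, j] <= spec.match_radius_px]

    tp = len(pairs)
    return MatchResult(tp, len(pred_a) - tp, len(gt_a) - tp, tuple(sorted(pairs)))


def compute_metrics(correct: int, all_detected: int, gt_count: int) -> CountMetrics:
    """Precision, recall and overall accuracy from raw counts.

    ``precision = correct/all_detected`` (0 with a warning when nothing was
    detected), ``recall = correct/gt_count``, ``overall`` their mean.
    """
    if gt_count <= 0:
        raise ValueError("gt_count must be positive")
    if correct > all_detected or correct > gt_count or correct < 0:
        raise ValueError(
            f"need 0 <= correct <= min(all_detected, gt_count); got "
            f"correct={correct}, all_detected={all_detected}, gt_count={gt_count}"
        )
    if all_detected == 0:
        logger.warning("compute_metrics: no detections at all; precision defined as 0")
        precision = 0.0
    else:
        precision = correct / all_detected
    recall = correct / gt_count
    return CountMetrics(
        correct=correct,
        all_detected=all_detected,
        gt_count=gt_count,
        precision=precision,
        recall=recall,
        overall_accuracy=(precision + recall) / 2.0,
    )


def load_ground_truth(path: str | Path) -> GroundTruthSet:
    """Read ground truth from a CSV with columns x,y."""
    df = pd.read_csv(path)
    return GroundTruthSet(df[["x", "y"]].to_numpy(dtype=float))


def save_ground_truth(gt: GroundTruthSet, path: str | Path) -> None:
    pd.DataFrame(gt.points, columns=["x", "y"]).to_csv(path, index=False)
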