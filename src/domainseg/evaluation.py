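"""Scoring predicted domain sets against reference definitions.

Detection (≥50% of a reference domain's residues assigned), split counting
(predicted domains each covering >50% of the reference), boundary accuracy
by intersection-over-union, the >75%-mutual-overlap correctness criterion,
and the grid search over the clustering thresholds (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .domains import DomainSet
from .postprocess import ClusterConfig, cluster_segments, refine_boundaries
from .structure import PairMatrix


@dataclass
class EvalRecord:
    """How one reference domain fared against a predicted domain set."""

    ref_index: int
    detected: bool
    n_split: int
    best_iou: float
    matched_pred_index: int | None


def iou(a: set[int], b: set[int]) -> float:
    """|a∩b| / |a∪b|; undefined (error) when both sets are empty."""
    union = a | b
    if not union:
        raise ValueError("IoU of two empty sets is undefined")
    return len(a & b) / len(union)


def detection(ref: DomainSet, pred: DomainSet) -> list[EvalRecord]:
    """Per-reference detection, split count and best-match IoU.

    A reference domain is detected if at least 50% of its residues are
    assigned to predicted domains (any of them); its split count is the
    number of predicted domains that each cover more than 50% of its
    residues; the matched prediction maximizes the intersection.
    """
    records: list[EvalRecord] = []
    pred_union = pred.assigned
    for k, r in enumerate(ref.domains):
        detected = len(r & pred_union) >= 0.5 * len(r)
        n_split = sum(1 for p in pred.domains if len(r & p) > 0.5 * len(r))
        best_idx, best_inter = None, 0
        for i, p in enumerate(pred.domains):
            inter = len(r & p)
            if inter > best_inter:
                best_idx, best_inter = i, inter
        best = iou(r, pred.domains[best_idx]) if best_idx is not None else 0.0
        records.append(EvalRecord(k, detected, n_split, best, best_idx))
    return records


def correct_fraction(
    refs: DomainSet, preds: DomainSet, overlap: float = 0.75
) -> float:
    """Fraction of reference domains with a mutually >overlap-covering match.

    A reference domain is correct iff some predicted domain shares strictly
    more than ``overlap`` of the residues of *both* domains.
    """
    if not refs.domains:
        raise ValueError("no reference domains")
    n_correct = 0
    for r in refs.domains:
        for p in preds.domains:
            inter = len(r & p)
            if inter > overlap * len(r) and inter > overlap * len(p):
                n_correct += 1
                break
    return n_correct / len(refs.domains)


@dataclass
class OptimizationConfig:
    """Grid over the clustering thresholds and the correctness criterion."""

    p_min_grid: Sequence[float]
    ratio_max_grid: Sequence[float]
    correctness_overlap: float = 0.75

    def __post_init__(self) -> None:
        if not len(self.p_min_grid) or not len(self.ratio_max_grid):
            raise ValueError("empty grid")


@dataclass
class ValidationItem:
    """One validation protein, pre-digested for the grid search: probability
    matrix, surviving segments, contact sets, length and reference truth."""

    prob: PairMatrix
    segments: list[tuple[int, ...]]
    contacts: list[set[int]]
    truth: DomainSet

    @property
    def L(self) -> int:
        return self.prob.length


def grid_search_xy(
    items: Sequence[ValidationItem],
    config: OptimizationConfig,
    base: ClusterConfig = ClusterConfig(),
) -> tuple[float, float]:
    """Exhaustive (p_min, ratio_max) search maximizing the pooled correct
    fraction over all reference domains; ties break toward the smallest
    p_min, then the smallest ratio_max."""
    from dataclasses import replace

    best_score = -1.0
    best_xy: tuple[float, float] | None = None
    for p_min in sorted(config.p_min_grid):
        for ratio_max in sorted(config.ratio_max_grid):
            cfg = replace(base, p_min=p_min, ratio_max=ratio_max)
            n_ref = n_correct = 0
            for item in items:
                clusters = cluster_segments(item.prob, item.segments, cfg)
                residue_sets = [
                    set().union(*(set(item.segments[s]) for s in c)) for c in clusters
                ]
                pred = refine_boundaries(residue_sets, item.contacts, item.L, cfg)
                n_ref += len(item.truth.domains)
                frac = correct_fraction(item.truth, pred, config.correctness_overlap)
                n_correct += round(frac * len(item.truth.domains))
            score = n_correct / n_ref if n_ref else 0.0
            if score > best_score + 1e-12:
                best_score = score
                best_xy = (p_min, ratio_max)
    assert best_xy is not None
    return best_xy


def summarize_iou(records: Sequence[EvalRecord]) -> dict:
    """Median/quartiles of best-match IoU (linear-interpolation quantiles)."""
    ious = np.array([r.best_iou for r in records])
    return {
        "median_iou": float(np.quantile(ious, 0.5)),
        "q1_iou": float(np.quantile(ious, 0.25)),
        "q3_iou": float(np.quantile(ious, 0.75)),
        "detection_rate": float(np.mean([r.detected for r in records])),
        "mean_n_split": float(np.mean([r.n_split for r in records])),
    }
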