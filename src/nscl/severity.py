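"""Mistake-severity metric and hierarchy-aware error decomposition.

A prediction is scored level by level against the label hierarchy, from the
coarsest partition down to the leaves.  A mismatch at level ``l`` counts as
an error there and — because an error at a coarse level is inherited by
every refinement below it — propagates to all deeper levels.  The
per-sample severity is the fraction of levels in error; a classifier's
severity is the mean over samples.  High severity means mistakes start at
broad, semantically distant categories; low severity means mistakes are
confined to fine distinctions within the correct coarse group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hierarchy import LabelHierarchy

__all__ = [
    "LevelPredictions",
    "SeverityReport",
    "per_level_mismatch",
    "sample_severity",
    "classifier_severity",
    "per_level_accuracy",
    "hierarchy_ordered_confusion",
]


@dataclass(frozen=True)
class LevelPredictions:
    """Per-level predicted and true cluster ids, both ``(m, L)``."""

    predictions: np.ndarray
    truths: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.predictions, dtype=int)
        t = np.asarray(self.truths, dtype=int)
        if p.ndim != 2 or p.shape != t.shape:
            raise ValueError(
                f"predictions {p.shape} and truths {t.shape} must be "
                "matching (m, L) matrices"
            )
        object.__setattr__(self, "predictions", p)
        object.__setattr__(self, "truths", t)

    @property
    def m(self) -> int:
        return int(self.predictions.shape[0])

    @property
    def n_levels(self) -> int:
        return int(self.predictions.shape[1])


@dataclass(frozen=True)
class SeverityReport:
    """Per-sample severities, their mean, and per-level mismatch rates."""

    per_sample: np.ndarray
    mean: float
    per_level_mismatch_rate: np.ndarray
    m: int

    def __post_init__(self) -> None:
        s = np.asarray(self.per_sample, dtype=float)
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("severities must lie in [0, 1]")
        if abs(float(np.mean(s)) - self.mean) > 1e-12:
            raise ValueError("mean must equal the mean of per-sample values")
        object.__setattr__(self, "per_sample", s)


def per_level_mismatch(levels: LevelPredictions) -> np.ndarray:
    """Binary (m, L) matrix: 1 where prediction != truth, before any
    propagation."""
    return (levels.predictions != levels.truths).astype(int)


def sample_severity(mismatch_row, propagate: bool = True) -> float:
    """Severity of one sample from its per-level mismatch vector.

    With propagation (the default), every level at and below the first
    mismatch counts as an error: ``(L - first_error + 1) / L`` (0 when the
    whole path is correct).  Without propagation the raw mismatch fractions
    are averaged — a diagnostic view only.
    """
    s = np.asarray(mismatch_row, dtype=int).ravel()
    if s.size == 0:
        raise ValueError("mismatch vector must have at least one level")
    length = s.size
    if not propagate:
        return float(np.sum(s)) / length
    hits = np.flatnonzero(s)
    if hits.size == 0:
        return 0.0
    return float(length - hits[0]) / length


def classifier_severity(
    levels: LevelPredictions, propagate: bool = True
) -> SeverityReport:
    """Severity of a classifier: expectation of sample severities over the
    evaluation set, plus the per-level mismatch rates."""
    if levels.m < 1:
        raise ValueError("need at least one sample")
    mm = per_level_mismatch(levels)
    per_sample = np.array(
        [sample_severity(row, propagate=propagate) for row in mm]
    )
    return SeverityReport(
        per_sample=per_sample,
        mean=float(np.mean(per_sample)),
        per_level_mismatch_rate=mm.mean(axis=0),
        m=levels.m,
    )


def per_level_accuracy(levels: LevelPredictions) -> np.ndarray:
    """Accuracy at each hierarchy level: 1 − mean mismatch, coarse to fine."""
    return 1.0 - per_level_mismatch(levels).mean(axis=0)


def hierarchy_ordered_confusion(
    leaf_predictions,
    leaf_truths,
    hierarchy: LabelHierarchy,
    pseudocount: float = 0.5,
):
    """Hierarchy-ordered confusion counts and a negative-log error intensity.

    Rows (truth) and columns (prediction) follow a depth-first traversal of
    the hierarchy so leaves sharing coarse clusters are adjacent and
    within-group confusion shows as diagonal blocks.  The diagonal (correct
    classifications) is zeroed; off-diagonal error counts are normalised and
    mapped to ``-log((count + pseudocount) / (total + pseudocount * cells))``
    (Haldane–Anscombe-style pseudocount for empty cells).

    Returns a dict with ``counts``, ``intensity`` (None when there are no
    errors), ``leaf_order``, ``block_ids`` (coarsest-level cluster per
    ordered leaf), and the within-supergroup error fraction.
    """
    pred = np.asarray(leaf_predictions, dtype=int)
    truth = np.asarray(leaf_truths, dtype=int)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("leaf predictions/truths must be matching vectors")
    n = hierarchy.n_leaves
    if np.any(pred < 0) or np.any(pred >= n) or np.any(truth < 0) or np.any(truth >= n):
        raise ValueError(f"leaf indices must lie in 0..{n - 1}")

    order_labels = hierarchy.leaf_order()
    label_to_idx = {lab: i for i, lab in enumerate(hierarchy.leaf_labels)}
    order = [label_to_idx[lab] for lab in order_labels]
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)

    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (pos[truth], pos[pred]), 1)
    np.fill_diagonal(counts, 0)
    total_errors = int(counts.sum())

    block_ids = np.array(
        [hierarchy.ancestor_at_level(lab, 1) for lab in order_labels]
    )
    within = float(
        counts[block_ids[:, None] == block_ids[None, :]].sum() / total_errors
    ) if total_errors else float("nan")

    intensity = None
    if total_errors:
        cells = n * n - n
        norm = (counts + pseudocount) / (total_errors + pseudocount * cells)
        with np.errstate(divide="ignore"):
            intensity = -np.log(norm)
        np.fill_diagonal(intensity, 0.0)
    return {
        "counts": counts,
        "intensity": intensity,
        "leaf_order": order_labels,
        "block_ids": block_ids,
        "total_errors": total_errors,
        "within_group_error_fraction": within,
    }
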