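"""Training losses: cosine embedding regression, weighted cross-entropy,
and their combination.

The objective at every cascade stage is

    L = alpha * L_R + beta * L_CCE

where ``L_R`` pulls each sample's latent representation toward the word
embedding of its (stage-level) class and ``L_CCE`` is the class-weighted
categorical cross-entropy.  The schedule ties the weights: for alpha < 1,
beta = 1 - alpha (a convex mix); for alpha >= 1, beta is fixed at 1 and the
regression term is simply up-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LossWeights",
    "cosine_alignment_loss",
    "class_weights_from_counts",
    "weighted_cross_entropy",
    "resolve_weight_schedule",
    "combined_loss",
    "LOG_EPS",
]

logger = logging.getLogger(__name__)

#: floor applied to probabilities before taking logs
LOG_EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Weights (alpha, beta) of the regression and classification terms."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha < 1 and abs(self.beta - (1.0 - self.alpha)) > 1e-9:
            raise ValueError("schedule violated: alpha<1 requires beta=1-alpha")
        if self.alpha >= 1 and abs(self.beta - 1.0) > 1e-9:
            raise ValueError("schedule violated: alpha>=1 requires beta=1")


def resolve_weight_schedule(alpha: float) -> LossWeights:
    """Resolve the (alpha, beta) pair from the regression weight alpha.

    alpha < 1 -> beta = 1 - alpha; alpha >= 1 -> beta = 1.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    beta = 1.0 - alpha if alpha < 1 else 1.0
    return LossWeights(float(alpha), float(beta))


def cosine_alignment_loss(latent: np.ndarray, targets: np.ndarray) -> float:
    """Mean over samples of ``1 - cos(w_i, r_i)``; in [0, 2].

    0 for perfectly aligned pairs, 1 for orthogonal, 2 for anti-aligned.
    Invariant to positive rescaling of either argument.
    """
    latent = np.asarray(latent, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if latent.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: latent {latent.shape} vs targets {targets.shape}"
        )
    if latent.ndim == 1:
        latent = latent[None, :]
        targets = targets[None, :]
    for name, arr in (("latent", latent), ("target", targets)):
        norms = np.linalg.norm(arr, axis=1)
        if np.any(norms == 0):
            row = int(np.argmin(norms))
            raise ValueError(f"zero-norm {name} vector at row {row}")
    cos = np.sum(latent * targets, axis=1) / (
        np.linalg.norm(latent, axis=1) * np.linalg.norm(targets, axis=1)
    )
    return float(np.mean(1.0 - cos))


def class_weights_from_counts(counts: Sequence[int]) -> np.ndarray:
    """Inverse-frequency class weights ``w_c = N / (K * n_c)``.

    Balanced counts give all-ones, so the weighted loss coincides with the
    unweighted one in the balanced regime.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if np.any(counts <= 0):
        missing = int(np.argmin(counts))
        raise ValueError(
            f"class {missing} has no samples in the training split"
        )
    total = counts.sum()
    return total / (counts.size * counts.astype(float))


def weighted_cross_entropy(
    scores: np.ndarray,
    targets: Sequence[int],
    weights: Sequence[float] | None = None,
) -> float:
    """Class-weighted mean negative log-likelihood.

    Each sample contributes ``-log(score at its true class)`` scaled by its
    class weight; the sum is normalised by the total applied weight, so the
    loss scale stays comparable across imbalance regimes.  Zero scores at a
    true class are clamped at ``LOG_EPS`` and logged.
    """
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if scores.ndim != 2:
        raise ValueError("scores must be (m, K)")
    m, k = scores.shape
    if targets.shape != (m,):
        raise ValueError("one target index per score row required")
    if np.any(targets < 0) or np.any(targets >= k):
        raise ValueError(f"target indices must lie in 0..{k - 1}")
    if weights is None:
        weights = np.ones(k)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (k,) or np.any(weights <= 0):
        raise ValueError("weights must be positive, one per class")
    p = scores[np.arange(m), targets]
    if np.any(p <= 0):
        logger.warning(
            "clamping %d zero/negative true-class scores at eps=%g",
            int(np.sum(p <= 0)), LOG_EPS,
        )
        p = np.maximum(p, LOG_EPS)
    w = weights[targets]
    return float(np.sum(w * -np.log(p)) / np.sum(w))


def combined_loss(
    weights: LossWeights, regression: float, classification: float
) -> float:
    """``alpha * regression + beta * classification``."""
    if not (np.isfinite(regression) and np.isfinite(classification)):
        raise ValueError("loss terms must be finite")
    if regression < 0 or classification < 0:
        raise ValueError("loss terms must be non-negative")
    return weights.alpha * regression + weights.beta * classification
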