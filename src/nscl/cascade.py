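"""Coarse-to-fine cascade classifiers and the seven training mechanisms.

A cascade model is a stack of feature-extractor blocks grown one stage at a
time; each stage ``l`` carries its own output block (projection to the word
embedding dimension ``u``, a rectifier, and a softmax head over the stage's
classes).  The mechanisms differ in three switches:

==========  =================  ==============  =====================
mechanism   stage targets      earlier blocks  stages
==========  =================  ==============  =====================
E2E         leaf classes       (single stage)  1, full depth
HE2E        leaf classes       (single stage)  1, full depth + Eq.-style
                                               combined embedding loss
CL          leaf classes       frozen          one per block
NCL         leaf classes       fine-tuned      one per block
SCL         hierarchy level l  frozen          one per hierarchy level
NSCL        hierarchy level l  fine-tuned      one per hierarchy level
RHCL        random hierarchy   fine-tuned      one per hierarchy level
==========  =================  ==============  =====================

The networks are intentionally small (dense blocks, Adam, hand-written
backprop in numpy): the object of study is the training *mechanism* and the
error structure it induces, not benchmark accuracy.  The analytic backward
pass doubles as the exact input-gradient oracle used by the saliency module.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hierarchy import LabelEmbeddingTable, LabelHierarchy, random_hierarchy
from .losses import (
    LossWeights,
    class_weights_from_counts,
    resolve_weight_schedule,
)

__all__ = [
    "MECHANISMS",
    "DataBatch",
    "BlockSpec",
    "StageSpec",
    "TrainConfig",
    "CascadeModel",
    "build_stage_targets",
    "grow_model",
    "train_stage",
    "train_cascade",
    "predict_leaf",
    "predict_levels",
    "stage_embedding_matrix",
]

logger = logging.getLogger(__name__)

MECHANISMS = ("E2E", "HE2E", "CL", "SCL", "NCL", "NSCL", "RHCL")
#: mechanisms that require a LabelHierarchy
SEMANTIC_MECHANISMS = ("SCL", "NSCL", "RHCL")
#: mechanisms whose pre-existing blocks stay frozen during a stage
FROZEN_MECHANISMS = ("CL", "SCL")

_COS_EPS = 1e-12

#: registry of feature-block kinds; 'affine' is filled in below
_BLOCK_KINDS: dict[str, type] = {"affine": None}


# ---------------------------------------------------------------------------
# Data containers and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DataBatch:
    """Inputs plus integer leaf targets.

    ``inputs`` may be tabular ``(m, d)`` or image-shaped ``(m, H, W[, C])``;
    models flatten internally and remember the spatial shape.
    """

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.inputs, dtype=float)
        y = np.asarray(self.targets, dtype=int)
        if x.ndim < 2:
            raise ValueError("inputs must be at least 2-D (m, features...)")
        if y.shape != (x.shape[0],):
            raise ValueError("one leaf target per input row required")
        if not np.all(np.isfinite(x)):
            raise ValueError("inputs must be finite")
        if np.any(y < 0):
            raise ValueError("targets must be non-negative class indices")
        object.__setattr__(self, "inputs", x)
        object.__setattr__(self, "targets", y)

    @property
    def m(self) -> int:
        return int(self.inputs.shape[0])

    @property
    def feature_shape(self) -> tuple[int, ...]:
        return tuple(self.inputs.shape[1:])


@dataclass(frozen=True)
class BlockSpec:
    """Description of one feature-extractor block (pluggable kinds)."""

    kind: str = "affine"
    width: int = 32

    def __post_init__(self) -> None:
        if self.kind not in _BLOCK_KINDS:
            raise ValueError(
                f"unknown block kind {self.kind!r}; registered: "
                f"{sorted(_BLOCK_KINDS)}"
            )
        if self.width <= 0:
            raise ValueError("block width must be positive")


@dataclass(frozen=True)
class StageSpec:
    """One cascade stage: level index, head width, block, epochs, scope."""

    level: int
    n_classes: int
    block: BlockSpec
    epochs: int
    trainable_scope: str = "new-only"  # "new-only" (cascade) | "all" (nested)

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("stage level is 1-based")
        if self.n_classes < 1:
            raise ValueError("stage needs at least one class")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.trainable_scope not in ("new-only", "all"):
            raise ValueError("trainable_scope must be 'new-only' or 'all'")


@dataclass(frozen=True)
class TrainConfig:
    """Mechanism, optimiser, and loss settings for a cascade run."""

    mechanism: str = "NSCL"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    epochs_per_stage: int | tuple = 10
    alpha: float = 0.0
    class_weighting: str = "proportional"  # or "none"
    grad_clip_norm: float = 5.0  # global gradient-norm ceiling (0 disables)
    #: nested stages train only their new blocks for this many warm-up
    #: epochs before fine-tuning everything (capped at epochs - 1 so a
    #: nested stage always fine-tunes); shields pre-trained blocks from
    #: the arbitrary early gradients of freshly initialised stage blocks
    nested_warmup_epochs: int = 5
    block: BlockSpec | tuple = BlockSpec()  # one spec, or one per stage
    embedding_dim: int = 16
    n_blocks: int | None = None  # depth for E2E/HE2E/CL/NCL without hierarchy
    rhcl_nested: bool = False  # RHCL is SCL (frozen) on the random grouping

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimiser family is supported")
        if self.class_weighting not in ("proportional", "none"):
            raise ValueError("class_weighting must be 'proportional' or 'none'")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def loss_weights(self) -> LossWeights:
        return resolve_weight_schedule(self.alpha)

    def block_for_stage(self, stage_no: int) -> BlockSpec:
        if isinstance(self.block, BlockSpec):
            return self.block
        return self.block[min(stage_no - 1, len(self.block) - 1)]

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "TrainConfig":
        if name not in TRAIN_PRESETS:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(TRAIN_PRESETS)}"
            )
        return cls(**{**TRAIN_PRESETS[name], **overrides})


#: named training presets.  ``fixture_tiny`` is sized for the planted
#: two-level synthetic world: the block width sits just above the
#: supergroup count, so the first stage's representation is a genuine
#: bottleneck, and the heavily weighted embedding-regression term
#: (alpha = 7, the top of the explored schedule) makes the coarse stage
#: imprint its grouping — semantic or random — onto that bottleneck.
#: The cifar/chexpert presets mirror the published layer widths and
#: per-stage epoch budgets at desk scale; tabular_1d mirrors the 1-D
#: tabular architecture.
TRAIN_PRESETS: dict[str, dict] = {
    "fixture_tiny": dict(
        block=BlockSpec(width=6), epochs_per_stage=(30, 15),
        learning_rate=1e-3, alpha=7.0, batch_size=64,
    ),
    "cifar_small": dict(
        block=BlockSpec(width=256), epochs_per_stage=50, learning_rate=1e-3,
    ),
    "chexpert_small": dict(
        block=(BlockSpec(width=512), BlockSpec(width=256),
               BlockSpec(width=256), BlockSpec(width=128)),
        epochs_per_stage=(35, 40, 45, 50), learning_rate=1e-4,
    ),
    "tabular_1d": dict(
        block=(BlockSpec(width=16), BlockSpec(width=32),
               BlockSpec(width=64), BlockSpec(width=32)),
        learning_rate=1e-4, batch_size=128,
    ),
}


# ---------------------------------------------------------------------------
# Blocks (pluggable; 'affine' is the stock kind)
# ---------------------------------------------------------------------------

class AffineBlock:
    """Dense feature block: ``h = relu(x W + b)``."""

    kind = "affine"

    def __init__(self, in_dim: int, width: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)  # He init for the rectifier
        self.W = rng.normal(0.0, scale, size=(in_dim, width))
        self.b = np.zeros(width)

    @property
    def out_dim(self) -> int:
        return self.W.shape[1]

    def forward(self, x: np.ndarray):
        pre = x @ self.W + self.b
        return np.maximum(pre, 0.0), (x, pre)

    def backward(self, dh: np.ndarray, cache):
        x, pre = cache
        dpre = dh * (pre > 0)
        return {"W": x.T @ dpre, "b": dpre.sum(axis=0)}, dpre @ self.W.T

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}


_BLOCK_KINDS["affine"] = AffineBlock


def register_block_kind(name: str, cls) -> None:
    """Register an additional feature-block kind (e.g. a convolutional one)."""
    _BLOCK_KINDS[name] = cls


class OutputBlock:
    """Stage head: projection to ``u`` units, rectifier, affine softmax head.

    The pre-rectifier projection output is the latent representation ``r``
    supervised by the embedding-regression loss (a post-rectifier latent is
    non-negative and can vanish, which degenerates cosine alignment).
    """

    def __init__(self, in_dim: int, u: int, n_classes: int,
                 rng: np.random.Generator):
        self.Wp = rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(in_dim, u))
        self.bp = np.zeros(u)
        # zero-init head: initial CE is exactly log K whatever the scale of
        # the (possibly heavily fine-tuned) upstream activations
        self.Wh = np.zeros((u, n_classes))
        self.bh = np.zeros(n_classes)

    @property
    def n_classes(self) -> int:
        return self.Wh.shape[1]

    @property
    def u(self) -> int:
        return self.Wp.shape[1]

    def forward(self, x: np.ndarray):
        latent = x @ self.Wp + self.bp
        hidden = np.maximum(latent, 0.0)
        logits = hidden @ self.Wh + self.bh
        return latent, logits, (x, latent, hidden)

    def backward(self, dlatent_reg, dlogits, cache):
        x, latent, hidden = cache
        dWh = hidden.T @ dlogits
        dbh = dlogits.sum(axis=0)
        dhidden = dlogits @ self.Wh.T
        dlatent = dhidden * (latent > 0)
        if dlatent_reg is not None:
            dlatent = dlatent + dlatent_reg
        grads = {
            "Wp": x.T @ dlatent, "bp": dlatent.sum(axis=0),
            "Wh": dWh, "bh": dbh,
        }
        return grads, dlatent @ self.Wp.T

    def params(self) -> dict[str, np.ndarray]:
        return {"Wp": self.Wp, "bp": self.bp, "Wh": self.Wh, "bh": self.bh}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# The cascade model
# ---------------------------------------------------------------------------

class CascadeModel:
    """Staged feature blocks plus one retained output block per stage."""

    def __init__(self, input_shape: Sequence[int], embedding_dim: int):
        self.input_shape = tuple(int(s) for s in input_shape)
        self.input_dim = int(np.prod(self.input_shape))
        self.u = int(embedding_dim)
        self.feature_blocks: list = []
        self.output_blocks: list[OutputBlock] = []
        #: number of feature blocks on each stage's forward path
        self.stage_depths: list[int] = []

    # -- structure ----------------------------------------------------------

    @property
    def n_stages(self) -> int:
        return len(self.output_blocks)

    @property
    def head_widths(self) -> list[int]:
        return [ob.n_classes for ob in self.output_blocks]

    def _flatten(self, inputs: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs, dtype=float)
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} != model shape {self.input_shape}"
            )
        return x.reshape(x.shape[0], -1)

    # -- forward / backward -------------------------------------------------

    def forward(self, inputs: np.ndarray, stage: int | None = None):
        """Run through feature blocks 1..stage and stage's output block.

        Returns ``(latent, probs, caches)``; ``stage`` is 1-based and
        defaults to the deepest stage.
        """
        if self.n_stages == 0:
            raise RuntimeError("model has no stages; grow it first")
        stage = self.n_stages if stage is None else stage
        if not 1 <= stage <= self.n_stages:
            raise ValueError(f"stage must be in 1..{self.n_stages}")
        h = self._flatten(inputs)
        fcaches = []
        for blk in self.feature_blocks[:self.stage_depths[stage - 1]]:
            h, cache = blk.forward(h)
            fcaches.append(cache)
        latent, logits, ocache = self.output_blocks[stage - 1].forward(h)
        return latent, _softmax(logits), (stage, fcaches, ocache)

    def backward(self, dlatent_reg, dlogits, caches):
        """Backprop stage gradients; returns (param grads, input gradient)."""
        stage, fcaches, ocache = caches
        grads: dict[str, dict[str, np.ndarray]] = {}
        ograds, dh = self.output_blocks[stage - 1].backward(
            dlatent_reg, dlogits, ocache
        )
        grads[f"output/{stage}"] = ograds
        for idx in range(stage - 1, -1, -1):
            bgrads, dh = self.feature_blocks[idx].backward(dh, fcaches[idx])
            grads[f"feature/{idx + 1}"] = bgrads
        dx = dh.reshape((-1,) + self.input_shape)
        return grads, dx

    def input_gradient(
        self, inputs: np.ndarray, class_index: int, stage: int | None = None
    ) -> np.ndarray:
        """Exact gradient of the target-class logit w.r.t. the inputs."""
        latent, probs, caches = self.forward(inputs, stage)
        k = self.output_blocks[caches[0] - 1].n_classes
        if not 0 <= class_index < k:
            raise ValueError(f"class index {class_index} outside 0..{k - 1}")
        dlogits = np.zeros((inputs.shape[0], k))
        dlogits[:, class_index] = 1.0
        _, dx = self.backward(None, dlogits, caches)
        return dx

    # -- bookkeeping --------------------------------------------------------

    def named_blocks(self):
        for i, blk in enumerate(self.feature_blocks, start=1):
            yield f"feature/{i}", blk
        for i, blk in enumerate(self.output_blocks, start=1):
            yield f"output/{i}", blk

    def block_checksums(self) -> dict[str, str]:
        """SHA-256 per block over its serialised parameters (freeze audits)."""
        out = {}
        for name, blk in self.named_blocks():
            digest = hashlib.sha256()
            for pname in sorted(blk.params()):
                digest.update(np.ascontiguousarray(blk.params()[pname]).tobytes())
            out[name] = digest.hexdigest()
        return out

    # -- persistence (JSON so runs stay plain text) -------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        store = {
            name: {p: arr.tolist() for p, arr in blk.params().items()}
            for name, blk in self.named_blocks()
        }
        manifest = {
            "input_shape": list(self.input_shape),
            "embedding_dim": self.u,
            "block_kinds": [blk.kind for blk in self.feature_blocks],
            "block_widths": [blk.out_dim for blk in self.feature_blocks],
            "head_widths": self.head_widths,
            "stage_depths": self.stage_depths,
            "checksums": self.block_checksums(),
        }
        (directory / "parameters.json").write_text(json.dumps(store))
        (directory / "model.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "CascadeModel":
        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        store = json.loads((directory / "parameters.json").read_text())
        model = cls(manifest["input_shape"], manifest["embedding_dim"])
        rng = np.random.default_rng(0)
        in_dim = model.input_dim
        for i, (kind, width) in enumerate(
            zip(manifest["block_kinds"], manifest["block_widths"]), start=1
        ):
            blk = _BLOCK_KINDS[kind](in_dim, width, rng)
            for p, arr in store[f"feature/{i}"].items():
                setattr(blk, p, np.asarray(arr, dtype=float))
            model.feature_blocks.append(blk)
            in_dim = width
        for i, k in enumerate(manifest["head_widths"], start=1):
            depth = manifest["stage_depths"][i - 1]
            width = manifest["block_widths"][depth - 1]
            ob = OutputBlock(width, model.u, k, rng)
            for p, arr in store[f"output/{i}"].items():
                setattr(ob, p, np.asarray(arr, dtype=float))
            model.output_blocks.append(ob)
        model.stage_depths = [int(d) for d in manifest["stage_depths"]]
        return model


# ---------------------------------------------------------------------------
# Stage construction and training
# ---------------------------------------------------------------------------

def build_stage_targets(
    hierarchy: LabelHierarchy, leaf_targets: Sequence[int]
) -> np.ndarray:
    """Per-level target matrix (m, L): column l is each sample's level-(l+1)
    ancestor cluster id.  Leaf indices follow ``hierarchy.leaf_labels``."""
    y = np.asarray(leaf_targets, dtype=int)
    if np.any(y < 0) or np.any(y >= hierarchy.n_leaves):
        bad = y[(y < 0) | (y >= hierarchy.n_leaves)][0]
        raise ValueError(f"leaf target {bad} not present in the hierarchy")
    return hierarchy.assignments[y, :]


def stage_embedding_matrix(
    hierarchy: LabelHierarchy, table: LabelEmbeddingTable, level: int
) -> np.ndarray:
    """Embedding target per level-``level`` cluster: centroid of the member
    leaves' embeddings (a singleton cluster keeps its own leaf vector)."""
    vecs = {lab: table.vector(lab) for lab in hierarchy.leaf_labels}
    clusters = hierarchy.clusters_at_level(level)
    out = np.zeros((len(clusters), table.u))
    for cid, members in clusters.items():
        out[cid] = np.mean([vecs[m] for m in members], axis=0)
    return out


def grow_model(model: CascadeModel, stage: StageSpec,
               rng: np.random.Generator, n_blocks: int = 1) -> CascadeModel:
    """Append freshly initialised feature block(s) and the stage's output
    block; pre-existing blocks are untouched (checksum-audited).

    ``n_blocks > 1`` grows a multi-block stage (end-to-end models build
    their full depth in a single stage)."""
    if stage.level != model.n_stages + 1:
        raise ValueError(
            f"stage level {stage.level} does not extend current depth "
            f"{model.n_stages}"
        )
    block_cls = _BLOCK_KINDS[stage.block.kind]
    before = model.block_checksums()
    for _ in range(n_blocks):
        in_dim = (model.feature_blocks[-1].out_dim if model.feature_blocks
                  else model.input_dim)
        model.feature_blocks.append(block_cls(in_dim, stage.block.width, rng))
    model.output_blocks.append(
        OutputBlock(stage.block.width, model.u, stage.n_classes, rng)
    )
    model.stage_depths.append(len(model.feature_blocks))
    after = model.block_checksums()
    if any(after[name] != digest for name, digest in before.items()):
        raise RuntimeError("grow_model mutated a pre-existing block")
    return model


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, blocks: dict[str, object],
             grads: dict[str, dict[str, np.ndarray]]) -> None:
        self.t += 1
        for bname, bgrads in grads.items():
            blk = blocks[bname]
            for pname, g in bgrads.items():
                key = f"{bname}/{pname}"
                if key not in self.m:
                    self.m[key] = np.zeros_like(g)
                    self.v[key] = np.zeros_like(g)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
                mhat = self.m[key] / (1 - self.beta1**self.t)
                vhat = self.v[key] / (1 - self.beta2**self.t)
                param = getattr(blk, pname)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_gradients(grads: dict[str, dict[str, np.ndarray]],
                    max_norm: float) -> None:
    """Rescale all gradients in place so their global L2 norm is bounded.

    Guards the nested stages against the occasional exploding step when the
    regression term is heavily up-weighted (alpha >> 1)."""
    if max_norm <= 0:
        return
    total = np.sqrt(sum(
        float(np.sum(g**2)) for bg in grads.values() for g in bg.values()
    ))
    if total > max_norm:
        scale = max_norm / total
        for bg in grads.values():
            for g in bg.values():
                g *= scale


def _cosine_grad(latent: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Value and d/dlatent of mean(1 - cos(target_i, latent_i)).

    Degenerate (near-zero-norm) latent rows contribute loss 1 and zero
    gradient; during optimisation they drift out of degeneracy via the
    classification term.
    """
    m = latent.shape[0]
    ln = np.linalg.norm(latent, axis=1)
    tn = np.linalg.norm(targets, axis=1)
    ok = (ln > _COS_EPS) & (tn > _COS_EPS)
    cos = np.zeros(m)
    grad = np.zeros_like(latent)
    if np.any(ok):
        l_ok, t_ok = latent[ok], targets[ok]
        ln_ok, tn_ok = ln[ok, None], tn[ok, None]
        cos_ok = np.sum(l_ok * t_ok, axis=1, keepdims=True) / (ln_ok * tn_ok)
        cos[ok] = cos_ok[:, 0]
        # d cos / d r = w/(|w||r|) - cos * r/|r|^2 ; loss is 1 - cos, mean over m
        grad[ok] = -(t_ok / (tn_ok * ln_ok) - cos_ok * l_ok / ln_ok**2) / m
    return float(np.mean(1.0 - cos)), grad


def train_stage(
    model: CascadeModel,
    stage: StageSpec,
    data: DataBatch,
    stage_targets: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    embedding_targets: np.ndarray | None = None,
) -> list[float]:
    """Run gradient descent for one stage; returns the per-epoch loss history.

    In ``new-only`` scope the pre-existing blocks are excluded from the
    optimiser step, so their parameters stay bit-identical; in ``all`` scope
    every block on the stage's forward path is trainable.
    """
    y = np.asarray(stage_targets, dtype=int)
    if np.any(y >= stage.n_classes):
        raise ValueError("stage targets exceed the stage's class count")
    weights = resolve_weight_schedule(config.alpha)
    if weights.alpha > 0 and embedding_targets is None:
        raise ValueError(
            "alpha > 0 requires embedding regression targets for the stage"
        )
    if config.class_weighting == "proportional":
        counts = np.bincount(y, minlength=stage.n_classes)
        cls_w = class_weights_from_counts(np.maximum(counts, 1))
        cls_w[counts == 0] = 1.0  # classes absent from this stream
    else:
        cls_w = np.ones(stage.n_classes)

    blocks = dict(model.named_blocks())
    stage_idx = model.n_stages
    prev_depth = model.stage_depths[-2] if stage_idx > 1 else 0
    new_blocks = {
        f"feature/{i}"
        for i in range(prev_depth + 1, model.stage_depths[-1] + 1)
    } | {f"output/{stage_idx}"}
    if stage.trainable_scope == "new-only":
        trainable = new_blocks
        warmup = 0
    else:
        trainable = set(blocks)
        warmup = min(max(config.nested_warmup_epochs, 0),
                     max(stage.epochs - 1, 0))
    frozen_before = {
        name: digest for name, digest in model.block_checksums().items()
        if name not in trainable
    }

    opt = _Adam(config.learning_rate)
    x = data.inputs
    history: list[float] = []
    for epoch in range(stage.epochs):
        epoch_trainable = new_blocks if epoch < warmup else trainable
        order = rng.permutation(data.m)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, data.m, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            latent, probs, caches = model.forward(xb)
            # classification term (class-weighted CE on softmax scores)
            w = cls_w[yb]
            p_true = np.maximum(probs[np.arange(len(idx)), yb], 1e-12)
            l_cce = float(np.sum(w * -np.log(p_true)) / np.sum(w))
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), yb] -= 1.0
            dlogits *= (w / np.sum(w))[:, None]
            dlogits *= weights.beta
            # regression term (cosine alignment to stage embeddings)
            dlatent_reg = None
            l_reg = 0.0
            if weights.alpha > 0:
                targets_w = embedding_targets[yb]
                l_reg, greg = _cosine_grad(latent, targets_w)
                dlatent_reg = weights.alpha * greg
            loss = weights.alpha * l_reg + weights.beta * l_cce
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at stage {stage.level}: loss={loss}"
                )
            grads, _ = model.backward(dlatent_reg, dlogits, caches)
            step_grads = {n: g for n, g in grads.items()
                          if n in epoch_trainable}
            _clip_gradients(step_grads, config.grad_clip_norm)
            opt.step(blocks, step_grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))

    after = model.block_checksums()
    drifted = [n for n, d in frozen_before.items() if after[n] != d]
    if drifted:
        raise RuntimeError(f"freeze contract violated for blocks {drifted}")
    return history


def _stage_plan(hierarchy: LabelHierarchy | None, n_leaf_classes: int,
                config: TrainConfig) -> list[tuple[int, int]]:
    """(level, head width) per stage for the configured mechanism."""
    mech = config.mechanism
    if mech in ("E2E", "HE2E"):
        return [(1, n_leaf_classes)]
    if mech in ("CL", "NCL"):
        n_stages = config.n_blocks or (
            hierarchy.n_levels if hierarchy is not None else 2
        )
        return [(l, n_leaf_classes) for l in range(1, n_stages + 1)]
    counts = hierarchy.cluster_counts
    return [(l + 1, int(c)) for l, c in enumerate(counts)]


def train_cascade(
    data: DataBatch,
    hierarchy: LabelHierarchy | None,
    config: TrainConfig,
    embeddings: LabelEmbeddingTable | None = None,
) -> tuple[CascadeModel, dict]:
    """Train a cascade model under the configured mechanism.

    Returns the model and a report with per-stage loss histories, derived
    seeds, and the head-width schedule.  Semantic mechanisms (SCL, NSCL,
    RHCL) require a hierarchy; RHCL replaces it with a seeded random grouping
    of identical cluster sizes before training.  ``alpha > 0`` additionally
    requires a label-embedding table (its dimension overrides
    ``config.embedding_dim``).
    """
    mech = config.mechanism
    if mech in SEMANTIC_MECHANISMS and hierarchy is None:
        raise ValueError(f"mechanism {mech} requires a label hierarchy")
    if mech == "HE2E" and (config.alpha <= 0 or embeddings is None):
        raise ValueError(
            "HE2E is E2E with the combined loss: set alpha > 0 and provide "
            "label embeddings"
        )
    if config.alpha > 0 and embeddings is None:
        raise ValueError("alpha > 0 requires a label-embedding table")

    seed_seq = np.random.SeedSequence(config.seed)
    rhcl_seed, init_entropy = seed_seq.generate_state(2) % (2**31)
    train_hierarchy = hierarchy
    if mech == "RHCL":
        train_hierarchy = random_hierarchy(hierarchy, int(rhcl_seed))

    if hierarchy is not None:
        n_leaf = int(hierarchy.cluster_counts[-1])
    else:
        n_leaf = int(data.targets.max()) + 1
    plan = _stage_plan(train_hierarchy, n_leaf, config)

    u = embeddings.u if embeddings is not None else config.embedding_dim
    model = CascadeModel(data.feature_shape, u)
    if mech in ("E2E", "HE2E"):
        depth = config.n_blocks or (
            hierarchy.n_levels if hierarchy is not None else 2
        )
    else:
        depth = 1  # one block added per stage

    if train_hierarchy is not None:
        level_targets = build_stage_targets(train_hierarchy, data.targets)
    else:
        level_targets = None

    epochs = config.epochs_per_stage
    per_stage_epochs = (
        list(epochs) if isinstance(epochs, (list, tuple))
        else [int(epochs)] * len(plan)
    )
    if len(per_stage_epochs) != len(plan):
        raise ValueError(
            f"{len(per_stage_epochs)} epoch entries for {len(plan)} stages"
        )

    scope_all = mech in ("E2E", "HE2E", "NCL", "NSCL") or (
        mech == "RHCL" and config.rhcl_nested
    )
    stage_seeds = np.random.SeedSequence(int(init_entropy)).generate_state(
        len(plan)
    ) % (2**31)

    report: dict = {
        "mechanism": mech,
        "seed": config.seed,
        "stage_seeds": [int(s) for s in stage_seeds],
        "alpha": config.alpha,
        "head_widths": [],
        "histories": [],
    }
    if mech == "RHCL":
        report["rhcl_seed"] = int(rhcl_seed)
        report["train_hierarchy"] = train_hierarchy.to_json_dict()

    for stage_no, ((level, width), n_ep) in enumerate(
        zip(plan, per_stage_epochs), start=1
    ):
        rng = np.random.default_rng(int(stage_seeds[stage_no - 1]))
        scope = "all" if scope_all else "new-only"
        spec = StageSpec(level=stage_no, n_classes=width,
                         block=config.block_for_stage(stage_no),
                         epochs=n_ep, trainable_scope=scope)
        # E2E/HE2E grow their full depth in their single stage
        grow_model(model, spec, rng, n_blocks=depth)
        if mech in ("SCL", "NSCL", "RHCL"):
            y_stage = level_targets[:, level - 1]
            emb = (
                stage_embedding_matrix(train_hierarchy, embeddings, level)
                if config.alpha > 0 else None
            )
        else:
            y_stage = data.targets
            emb = (
                stage_embedding_matrix(
                    train_hierarchy, embeddings, train_hierarchy.n_levels
                )
                if (config.alpha > 0 and train_hierarchy is not None)
                else (embeddings.vectors if config.alpha > 0 else None)
            )
        history = train_stage(model, spec, data, y_stage, config, rng,
                              embedding_targets=emb)
        report["head_widths"].append(width)
        report["histories"].append(history)
        logger.info(
            "stage %d/%d (%d-way) trained for %d epochs; final loss %s",
            stage_no, len(plan), width, n_ep,
            f"{history[-1]:.4f}" if history else "n/a",
        )
    return model, report


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_leaf(model: CascadeModel, inputs: np.ndarray):
    """Leaf predictions from the deepest stage: argmax of its softmax scores
    (ties resolve to the lowest class index)."""
    _, probs, _ = model.forward(inputs)
    return probs.argmax(axis=1), probs


def predict_levels(
    model: CascadeModel,
    hierarchy: LabelHierarchy,
    inputs: np.ndarray,
    mode: str = "project-leaf",
) -> np.ndarray:
    """Per-level prediction matrix (m, L).

    ``project-leaf`` predicts the leaf once and reads ancestors off the
    hierarchy, so every model is scored on the same footing and predictions
    are hierarchy-consistent by construction.  ``stage-heads`` reads each
    stage's own head (cascade-style models only).
    """
    if mode == "project-leaf":
        pred, _ = predict_leaf(model, inputs)
        finest = hierarchy.assignments[:, -1]
        k = model.output_blocks[-1].n_classes
        if k != np.unique(finest).size:
            raise ValueError(
                f"final head width {k} != {np.unique(finest).size} "
                "finest-level clusters"
            )
        # ancestor rows per finest cluster id (nesting makes them unique)
        anc = np.zeros((np.unique(finest).size, hierarchy.n_levels), dtype=int)
        for cid in np.unique(finest):
            anc[cid] = hierarchy.assignments[finest == cid][0]
        return anc[pred]
    if mode == "stage-heads":
        if model.n_stages != hierarchy.n_levels:
            raise ValueError(
                f"stage-heads needs one stage per hierarchy level "
                f"({model.n_stages} stages vs {hierarchy.n_levels} levels); "
                "single-stage (end-to-end) models only support project-leaf"
            )
        cols = []
        for stage in range(1, model.n_stages + 1):
            _, probs, _ = model.forward(inputs, stage=stage)
            cols.append(probs.argmax(axis=1))
        return np.column_stack(cols)
    raise ValueError("mode must be 'project-leaf' or 'stage-heads'")
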