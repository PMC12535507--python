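"""Planted-hierarchy generators: offline stand-ins for label embeddings,
hierarchically structured datasets, and annotation-mask pairs.

The generators plant a two-level world: ``n_super`` well-separated
supergroup centres, each carrying ``leaves_per_super`` leaf classes packed
tightly around it.  ``delta_between`` controls the centre separation,
``delta_within`` the leaf spread, and ``noise_sigma`` the sample noise, so
the regime ``delta_within << noise_sigma << delta_between`` reproduces the
error structure the cascade method assumes: confusions concentrate inside
supergroups.  Everything is seed-deterministic; no downloads are needed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .cascade import DataBatch
from .hierarchy import LabelEmbeddingTable, LabelHierarchy, write_word2vec_text
from .saliency import BinaryMask, write_mask_png

__all__ = [
    "PlantedHierarchyConfig",
    "PRESETS",
    "simulate_label_embeddings",
    "simulate_classification_dataset",
    "simulate_mask_pair",
    "make_fixture_bundle",
]


@dataclass(frozen=True)
class PlantedHierarchyConfig:
    """Parameters of the planted two-level world.

    Defaults are the recovery-regime dataset used throughout the validation
    suite: 4 supergroups × 3 leaves, centre separation 20, leaf spread 1,
    sample noise 2, 200 samples per class.
    """

    n_super: int = 4
    leaves_per_super: int = 3
    u: int = 16
    delta_between: float = 20.0
    delta_within: float = 1.0
    feature_dim: int = 20
    noise_sigma: float = 2.0
    n_per_class: int = 200
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_super < 2 or self.leaves_per_super < 2:
            raise ValueError("need >=2 supergroups with >=2 leaves each")
        if min(self.u, self.feature_dim, self.n_per_class) < 1:
            raise ValueError("dimensions and counts must be positive")
        if min(self.delta_between, self.delta_within, self.noise_sigma) <= 0:
            raise ValueError("separations and noise must be positive")

    @property
    def n_classes(self) -> int:
        return self.n_super * self.leaves_per_super

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(
            f"s{i}_l{j}"
            for i in range(self.n_super)
            for j in range(self.leaves_per_super)
        )


#: named configurations for fixtures and smoke runs
PRESETS: dict[str, PlantedHierarchyConfig] = {
    "tiny": PlantedHierarchyConfig(
        n_super=2, leaves_per_super=2, u=8, delta_between=10.0,
        delta_within=0.5, feature_dim=10, noise_sigma=1.0, n_per_class=40,
    ),
    "recovery": PlantedHierarchyConfig(),
    "imbalanced": PlantedHierarchyConfig(
        n_super=2, leaves_per_super=2, u=8, delta_between=10.0,
        delta_within=0.5, feature_dim=10, noise_sigma=1.0, n_per_class=60,
    ),
}


def _separated_centres(n: int, dim: int, separation: float,
                       rng: np.random.Generator) -> np.ndarray:
    """n centres at exact pairwise distance ``separation`` (scaled random
    orthonormal frame when dim allows; rescaled Gaussian otherwise)."""
    if n <= dim:
        basis, _ = np.linalg.qr(rng.normal(size=(dim, n)))
        return basis.T * (separation / np.sqrt(2.0))
    centres = rng.normal(size=(n, dim))
    centres /= np.linalg.norm(centres, axis=1, keepdims=True)
    return centres * (separation / np.sqrt(2.0))


def _planted_hierarchy(config: PlantedHierarchyConfig) -> LabelHierarchy:
    a = np.column_stack([
        np.repeat(np.arange(config.n_super), config.leaves_per_super),
        np.arange(config.n_classes),
    ])
    return LabelHierarchy(config.leaf_labels, a)


def simulate_label_embeddings(
    config: PlantedHierarchyConfig,
) -> tuple[LabelEmbeddingTable, np.ndarray]:
    """Planted label embeddings plus the true supergroup partition.

    Each supergroup centre sits on a sphere at pairwise distance
    ``delta_between``; a leaf embedding is its centre plus an isotropic
    perturbation of scale ``delta_within``.  Labels are named ``s{i}_l{j}``.
    """
    rng = np.random.default_rng(config.seed)
    centres = _separated_centres(
        config.n_super, config.u, config.delta_between, rng
    )
    vectors = np.vstack([
        centres[i]
        + rng.normal(scale=config.delta_within / np.sqrt(config.u),
                     size=config.u)
        for i in range(config.n_super)
        for _ in range(config.leaves_per_super)
    ])
    partition = np.repeat(np.arange(config.n_super), config.leaves_per_super)
    return LabelEmbeddingTable(config.leaf_labels, vectors), partition


def simulate_classification_dataset(
    config: PlantedHierarchyConfig,
    imbalanced: bool = False,
    sample_seed: int | None = None,
) -> tuple[DataBatch, LabelHierarchy]:
    """Hierarchically structured class-conditional Gaussians.

    Class means are placed hierarchically in feature space (supergroup
    centres ``delta_between`` apart, leaf means ``delta_within`` around
    them); samples add isotropic noise of scale ``noise_sigma``.  Counts are
    exactly ``n_per_class`` per class, or drawn from a seeded multinomial
    (floored at 2) when ``imbalanced``.  ``sample_seed`` redraws the samples
    while keeping the planted means fixed — use it for train/test splits.
    """
    rng = np.random.default_rng(config.seed)
    centres = _separated_centres(
        config.n_super, config.feature_dim, config.delta_between, rng
    )
    means = np.vstack([
        centres[i]
        + rng.normal(scale=config.delta_within / np.sqrt(config.feature_dim),
                     size=config.feature_dim)
        for i in range(config.n_super)
        for _ in range(config.leaves_per_super)
    ])
    srng = np.random.default_rng(
        config.seed if sample_seed is None else sample_seed
    )
    k = config.n_classes
    if imbalanced:
        total = config.n_per_class * k
        probs = srng.dirichlet(np.full(k, 2.0))
        counts = np.maximum(srng.multinomial(total - 2 * k, probs) + 2, 2)
    else:
        counts = np.full(k, config.n_per_class)
    targets = np.repeat(np.arange(k), counts)
    noise = srng.normal(scale=config.noise_sigma,
                        size=(targets.size, config.feature_dim))
    inputs = means[targets] + noise
    order = srng.permutation(targets.size)
    return (
        DataBatch(inputs[order], targets[order]),
        _planted_hierarchy(config),
    )


def simulate_mask_pair(
    shape: tuple[int, int], overlap_fraction: float, seed: int = 0
) -> tuple[BinaryMask, BinaryMask, float]:
    """Two equal-area rectangle masks with a known, exact IOU.

    The second rectangle is the first shifted horizontally so that a
    fraction ``overlap_fraction`` of each rectangle's area intersects the
    other; the closed-form IOU from the placed pixel counts is returned
    alongside the masks.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    height, width = int(shape[0]), int(shape[1])
    rng = np.random.default_rng(seed)
    h = max(1, height // 3)
    w = max(2, width // 4)
    dx = int(round((1.0 - overlap_fraction) * w))
    if h > height or 2 * w > width:
        raise ValueError(f"shape {shape} too small for rectangle masks")
    row = int(rng.integers(0, height - h + 1))
    col = int(rng.integers(0, width - w - dx + 1))
    a = np.zeros((height, width), dtype=bool)
    b = np.zeros((height, width), dtype=bool)
    a[row:row + h, col:col + w] = True
    b[row:row + h, col + dx:col + dx + w] = True
    inter = h * (w - dx)
    union = h * (w + dx)
    return BinaryMask(a), BinaryMask(b), inter / union


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_dataset_csv(path: Path, batch: DataBatch,
                       labels: tuple[str, ...]) -> None:
    import pandas as pd

    frame = pd.DataFrame(
        batch.inputs,
        columns=[f"f{i}" for i in range(batch.inputs.shape[1])],
    )
    frame["label"] = [labels[t] for t in batch.targets]
    frame.to_csv(path, index=False, float_format="%.6g")


def make_fixture_bundle(preset: str, seed: int, out_dir) -> dict:
    """Write a self-contained on-disk fixture bundle for the CLI.

    Contents: word2vec-text label embeddings, labels list, hierarchy JSON,
    train/test CSVs, a PNG mask pair, a config echo, and a manifest with
    SHA-256 checksums.  Identical (preset, seed) pairs produce identical
    manifests.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from "
                         f"{sorted(PRESETS)}")
    config = replace(PRESETS[preset], seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    derived = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)

    table, _ = simulate_label_embeddings(config)
    write_word2vec_text(
        out / "embeddings.w2v.txt",
        {lab: vec for lab, vec in zip(table.labels, table.vectors)},
    )
    (out / "labels.txt").write_text("\n".join(table.labels) + "\n")

    imbalanced = preset == "imbalanced"
    train, hierarchy = simulate_classification_dataset(
        config, imbalanced=imbalanced, sample_seed=int(derived[0])
    )
    test_cfg = replace(config, n_per_class=max(10, config.n_per_class // 4))
    test, _ = simulate_classification_dataset(
        test_cfg, imbalanced=False, sample_seed=int(derived[1])
    )
    hierarchy.save_json(out / "hierarchy.json")
    _write_dataset_csv(out / "train.csv", train, config.leaf_labels)
    _write_dataset_csv(out / "test.csv", test, config.leaf_labels)

    mask_a, mask_b, mask_iou = simulate_mask_pair(
        (32, 32), overlap_fraction=0.5, seed=int(derived[2])
    )
    write_mask_png(out / "mask_saliency.png", mask_a)
    write_mask_png(out / "mask_annotation.png", mask_b)

    echo = {"preset": preset, "config": asdict(config),
            "mask_pair_iou": mask_iou}
    (out / "config.json").write_text(json.dumps(echo, indent=2))

    files = sorted(
        p.name for p in out.iterdir() if p.name != "manifest.json"
    )
    manifest = {
        "preset": preset,
        "seed": int(seed),
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
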