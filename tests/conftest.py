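import numpy as np
import pytest

from nscl.hierarchy import LabelEmbeddingTable, LabelHierarchy
from nscl.synthetic_data import (
    PRESETS,
    simulate_classification_dataset,
    simulate_label_embeddings,
)


@pytest.fixture
def token_source():
    """Tiny token -> vector lookup for label-embedding tests."""
    return {
        "car": np.array([1.0, 0.0]),
        "truck": np.array([0.9, 0.1]),
        "pleural": np.array([1.0, 0.0]),
        "effusion": np.array([0.0, 1.0]),
        "cat": np.array([-1.0, 0.2]),
    }


@pytest.fixture
def four_leaf_hierarchy():
    """Two supergroups of two leaves each: levels with 2 then 4 clusters."""
    a = np.array([[0, 0], [0, 1], [1, 2], [1, 3]])
    return LabelHierarchy(("a1", "a2", "b1", "b2"), a)


@pytest.fixture
def three_level_hierarchy():
    """8 leaves cut at 2 / 4 / 8 clusters (balanced binary nesting)."""
    leaves = tuple(f"leaf{i}" for i in range(8))
    a = np.column_stack([
        np.repeat([0, 1], 4),
        np.repeat([0, 1, 2, 3], 2),
        np.arange(8),
    ])
    return LabelHierarchy(leaves, a)


@pytest.fixture(scope="session")
def tiny_world():
    """Planted tiny dataset + hierarchy + embeddings (shared, read-only)."""
    cfg = PRESETS["tiny"]
    data, hierarchy = simulate_classification_dataset(cfg)
    table, partition = simulate_label_embeddings(cfg)
    return {"config": cfg, "data": data, "hierarchy": hierarchy,
            "table": table, "partition": partition}


@pytest.fixture
def random_table():
    """12 random (seeded) label embeddings for clustering invariants."""
    rng = np.random.default_rng(3)
    labels = tuple(f"w{i}" for i in range(12))
    return LabelEmbeddingTable(labels, rng.normal(size=(12, 5)))
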