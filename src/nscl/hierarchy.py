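"""Label hierarchies from semantic embeddings or prior knowledge.

Class labels are embedded in a continuous vector space (word2vec-style),
clustered agglomeratively into a dendrogram, and the dendrogram is cut at a
schedule of cluster counts to give nested partitions of the leaf classes —
the coarse-to-fine problems a cascade model trains on.  Hierarchies can also
be ingested directly from an edge list when prior domain knowledge (e.g. a
disease taxonomy) supplies the grouping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import pdist

__all__ = [
    "LabelEmbeddingTable",
    "Dendrogram",
    "LabelHierarchy",
    "embed_labels",
    "read_word2vec_text",
    "read_embeddings_json",
    "write_word2vec_text",
    "build_dendrogram",
    "cut_dendrogram",
    "hierarchy_from_edges",
    "random_hierarchy",
    "to_newick",
]

LINKAGES = ("average", "complete", "ward")
METRICS = ("cosine", "euclidean")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelEmbeddingTable:
    """One embedding vector per class-name label.

    Parameters
    ----------
    labels
        Ordered, unique class names.
    vectors
        Real matrix of shape ``(n_labels, u)``; every row finite with
        strictly positive norm.
    """

    labels: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        object.__setattr__(self, "vectors", vectors)
        if len(labels) != len(set(labels)):
            raise ValueError("labels must be unique")
        if vectors.shape[0] != len(labels):
            raise ValueError(
                f"{vectors.shape[0]} vectors for {len(labels)} labels"
            )
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embedding vectors must be finite")
        norms = np.linalg.norm(vectors, axis=1)
        if np.any(norms == 0):
            bad = labels[int(np.argmin(norms))]
            raise ValueError(f"zero-norm embedding for label {bad!r}")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def u(self) -> int:
        """Embedding dimension."""
        return int(self.vectors.shape[1])

    def vector(self, label: str) -> np.ndarray:
        return self.vectors[self.labels.index(label)]

    def normalized(self) -> np.ndarray:
        """Rows scaled to unit L2 norm (cosine geometry)."""
        return self.vectors / np.linalg.norm(self.vectors, axis=1, keepdims=True)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` is the scipy linkage matrix: row ``i`` merges nodes
    ``(merges[i,0], merges[i,1])`` at height ``merges[i,2]`` into node
    ``n_leaves + i``.
    """

    leaf_labels: tuple[str, ...]
    merges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaf_labels", tuple(self.leaf_labels))
        merges = np.asarray(self.merges, dtype=float)
        object.__setattr__(self, "merges", merges)
        n = len(self.leaf_labels)
        if merges.shape[0] != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {merges.shape[0]}")
        heights = merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")
        seen = merges[:, :2].astype(int).ravel()
        leaves = seen[seen < n]
        if sorted(leaves) != list(range(n)):
            raise ValueError("every leaf must appear exactly once in merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


@dataclass(frozen=True)
class LabelHierarchy:
    """Nested partitions of the leaf-label set across ``L`` levels.

    ``assignments[i, l]`` is the dense cluster id of leaf ``i`` at level
    ``l + 1`` (levels are 1-based in the public API; level ``L`` is the
    finest, leaf-level problem).  A single virtual root sits above level 1.
    """

    leaf_labels: tuple[str, ...]
    assignments: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaf_labels", tuple(self.leaf_labels))
        a = np.asarray(self.assignments, dtype=int)
        if a.ndim != 2 or a.shape[0] != len(self.leaf_labels):
            raise ValueError("assignments must be (n_leaves, L)")
        object.__setattr__(self, "assignments", a)
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.leaf_labels)}
        )
        sizes = self.cluster_counts
        if np.any(np.diff(sizes) < 0):
            raise ValueError("cluster counts must be non-decreasing with depth")
        # nesting: leaves sharing a level-(l+1) cluster share the level-l one
        for l in range(1, a.shape[1]):
            for cid in np.unique(a[:, l]):
                parents = np.unique(a[a[:, l] == cid, l - 1])
                if parents.size != 1:
                    raise ValueError(
                        f"level-{l + 1} cluster {cid} spans {parents.size} "
                        f"level-{l} clusters; partitions are not nested"
                    )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_levels(self) -> int:
        return int(self.assignments.shape[1])

    @property
    def cluster_counts(self) -> np.ndarray:
        """Number of clusters at each level, coarse to fine."""
        return np.array(
            [np.unique(self.assignments[:, l]).size
             for l in range(self.assignments.shape[1])]
        )

    def ancestor_at_level(self, leaf: str, level: int) -> int:
        """Dense cluster id of ``leaf``'s ancestor at 1-based ``level``."""
        if leaf not in self._index:
            raise KeyError(f"unknown leaf label {leaf!r}")
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"level must be in 1..{self.n_levels}, got {level}")
        return int(self.assignments[self._index[leaf], level - 1])

    def clusters_at_level(self, level: int) -> dict[int, list[str]]:
        """Map cluster id -> member leaf labels at 1-based ``level``."""
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"level must be in 1..{self.n_levels}, got {level}")
        col = self.assignments[:, level - 1]
        out: dict[int, list[str]] = {}
        for i, cid in enumerate(col):
            out.setdefault(int(cid), []).append(self.leaf_labels[i])
        return out

    def leaf_order(self) -> list[str]:
        """Leaves in depth-first order (children in cluster-id order)."""
        keys = [tuple(self.assignments[i]) + (i,) for i in range(self.n_leaves)]
        return [self.leaf_labels[i] for _, i in
                sorted(zip(keys, range(self.n_leaves)))]

    def to_json_dict(self) -> dict:
        return {
            "leaf_labels": list(self.leaf_labels),
            "levels": [
                {str(cid): members
                 for cid, members in sorted(self.clusters_at_level(l).items())}
                for l in range(1, self.n_levels + 1)
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def from_json_dict(cls, payload: Mapping) -> "LabelHierarchy":
        leaves = list(payload["leaf_labels"])
        idx = {lab: i for i, lab in enumerate(leaves)}
        levels = payload["levels"]
        a = np.zeros((len(leaves), len(levels)), dtype=int)
        for l, part in enumerate(levels):
            for cid, members in part.items():
                for lab in members:
                    a[idx[lab], l] = int(cid)
        return cls(tuple(leaves), _densify(a))

    @classmethod
    def load_json(cls, path) -> "LabelHierarchy":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _densify(assignments: np.ndarray) -> np.ndarray:
    """Relabel every column to dense ids ordered by first leaf appearance."""
    a = np.asarray(assignments, dtype=int)
    out = np.empty_like(a)
    for l in range(a.shape[1]):
        mapping: dict[int, int] = {}
        for raw in a[:, l]:
            if raw not in mapping:
                mapping[raw] = len(mapping)
        out[:, l] = [mapping[raw] for raw in a[:, l]]
    return out


# ---------------------------------------------------------------------------
# Embedding ingestion
# ---------------------------------------------------------------------------

def _tokenize(label: str) -> list[str]:
    return [t for t in label.lower().replace("_", " ").split() if t]


def embed_labels(
    labels: Sequence[str], source: Mapping[str, Sequence[float]]
) -> LabelEmbeddingTable:
    """Look up one embedding per label in a token -> vector source.

    A multi-token label (``"pleural_effusion"``) maps to the arithmetic mean
    of its token vectors after lowercasing and splitting on whitespace and
    underscores.  If the source provides a phrase vector under the full
    (lowercased) label, that vector is used directly.
    """
    if not labels:
        raise ValueError("no labels given")
    rows = []
    for label in labels:
        if not label:
            raise ValueError("empty label name")
        key = label.lower()
        if key in source:
            rows.append(np.asarray(source[key], dtype=float))
            continue
        tokens = [t for t in _tokenize(label) if t in source]
        if not tokens:
            raise KeyError(
                f"label {label!r}: no token found in the embedding source"
            )
        rows.append(
            np.mean([np.asarray(source[t], dtype=float) for t in tokens], axis=0)
        )
    vectors = np.vstack(rows)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        bad = labels[int(np.argmin(norms))]
        raise ValueError(f"label {bad!r} resolved to a zero-norm vector")
    return LabelEmbeddingTable(tuple(labels), vectors)


def read_word2vec_text(path) -> dict[str, np.ndarray]:
    """Read word2vec text format: header ``count dim``, then one token+vector
    per line."""
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec text file must start with 'count dim'")
        count, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                continue
            out[parts[0]] = np.asarray(parts[1:dim + 1], dtype=float)
    if len(out) != count:
        warnings.warn(
            f"word2vec header declared {count} vectors, read {len(out)}"
        )
    return out


def write_word2vec_text(path, vectors: Mapping[str, Sequence[float]]) -> None:
    items = list(vectors.items())
    dim = len(np.asarray(items[0][1]))
    with open(path, "w") as fh:
        fh.write(f"{len(items)} {dim}\n")
        for token, vec in items:
            fh.write(token + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def read_embeddings_json(path) -> dict[str, np.ndarray]:
    """JSON dialect ``{label: [floats], ...}`` used for small fixtures."""
    with open(path) as fh:
        payload = json.load(fh)
    return {k: np.asarray(v, dtype=float) for k, v in payload.items()}


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def build_dendrogram(
    table: LabelEmbeddingTable,
    linkage_method: str = "average",
    metric: str = "cosine",
) -> Dendrogram:
    """Agglomeratively cluster label embeddings into a dendrogram.

    Vectors are L2-normalised before computing pairwise distances so both
    metrics act on the cosine geometry of the embedding sphere.  Determinism
    follows from scipy's fixed tie-breaking on the condensed distance matrix.
    """
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if table.n_labels < 2:
        raise ValueError("need at least 2 labels to build a dendrogram")
    dists = pdist(table.normalized(), metric=metric)
    merges = linkage(dists, method=linkage_method)
    return Dendrogram(table.labels, merges)


def cut_dendrogram(
    dendrogram: Dendrogram, cluster_counts: Sequence[int]
) -> LabelHierarchy:
    """Cut a dendrogram into nested partitions at the given cluster counts.

    Counts must be strictly increasing within ``2..n_leaves`` except that a
    trailing repeated count is permitted (it duplicates the leaf-level stage,
    as in the chest-radiograph preset 2,4,6,6).
    """
    counts = [int(c) for c in cluster_counts]
    if not counts:
        raise ValueError("cluster_counts must be non-empty")
    n = dendrogram.n_leaves
    for c in counts:
        if not 1 <= c <= n:
            raise ValueError(f"cluster count {c} outside 1..{n}")
    for prev, cur in zip(counts, counts[1:]):
        if cur < prev:
            raise ValueError(f"cluster counts must be non-decreasing: {counts}")
        if cur == prev and cur != counts[-1]:
            raise ValueError(
                f"repeated count {cur} only permitted at the end: {counts}"
            )
    col = {
        c: cut_tree(dendrogram.merges, n_clusters=c).ravel()
        for c in sorted(set(counts))
    }
    a = np.column_stack([col[c] for c in counts])
    return LabelHierarchy(dendrogram.leaf_labels, _densify(a))


# ---------------------------------------------------------------------------
# Prior-knowledge ingestion
# ---------------------------------------------------------------------------

def hierarchy_from_edges(
    edges: Iterable[tuple[str, str]], leaf_labels: Sequence[str]
) -> LabelHierarchy:
    """Build a hierarchy from (child, parent) edges of a rooted taxonomy.

    The graph may be a DAG; a node listing several parents is resolved to its
    first-listed parent with a warning, because staged training needs a tree.
    Levels are the depth strata of the resolved tree: the level-``l`` cluster
    of a leaf is its ancestor at depth ``l`` (the leaf itself once ``l``
    exceeds its depth).
    """
    import networkx as nx

    parent: dict[str, str] = {}
    graph = nx.DiGraph()
    for child, par in edges:
        graph.add_edge(child, par)
        if child in parent:
            if parent[child] != par:
                warnings.warn(
                    f"node {child!r} has multiple parents; keeping "
                    f"first-listed parent {parent[child]!r}"
                )
            continue
        parent[child] = par
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("hierarchy edges contain a cycle")
    roots = {p for p in parent.values() if p not in parent}
    if len(roots) != 1:
        raise ValueError(f"expected a single root, found {sorted(roots)}")
    (root,) = roots

    def path_to_root(node: str) -> list[str]:
        path = [node]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        return path[::-1]  # root .. node

    paths = {}
    for leaf in leaf_labels:
        if leaf not in parent:
            raise ValueError(f"orphan leaf {leaf!r}: no path to the root")
        paths[leaf] = path_to_root(leaf)
        if paths[leaf][0] != root:
            raise ValueError(f"leaf {leaf!r} does not reach the root")
    depth = max(len(p) - 1 for p in paths.values())
    a = np.zeros((len(leaf_labels), depth), dtype=int)
    names: list[dict[str, int]] = [{} for _ in range(depth)]
    for i, leaf in enumerate(leaf_labels):
        p = paths[leaf]
        for l in range(1, depth + 1):
            node = p[min(l, len(p) - 1)]
            a[i, l - 1] = names[l - 1].setdefault(node, len(names[l - 1]))
    return LabelHierarchy(tuple(leaf_labels), _densify(a))


# ---------------------------------------------------------------------------
# Randomised control hierarchy
# ---------------------------------------------------------------------------

def random_hierarchy(hierarchy: LabelHierarchy, seed: int) -> LabelHierarchy:
    """Random grouping with the same per-level cluster sizes and nesting.

    Leaf labels are permuted uniformly at random (seeded) and re-assigned to
    the existing cluster structure, which preserves, level by level, the
    multiset of cluster sizes.  This is the calibration baseline for
    semantically clustered hierarchies.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(hierarchy.n_leaves)
    a = np.empty_like(hierarchy.assignments)
    a[perm] = hierarchy.assignments  # leaf perm[i] takes slot i's ancestry
    return LabelHierarchy(hierarchy.leaf_labels, _densify(a))


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _newick_escape(name: str) -> str:
    if any(ch in name for ch in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(obj: Dendrogram | LabelHierarchy) -> str:
    """Serialise a dendrogram (with branch lengths) or hierarchy (unit
    branch lengths) as a Newick string."""
    if isinstance(obj, Dendrogram):
        root = to_tree(obj.merges)
        labels = obj.leaf_labels

        def render(node) -> str:
            if node.is_leaf():
                return _newick_escape(labels[node.id])
            left = render(node.left)
            right = render(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.8g},{right}:{dr:.8g})"

        return render(root) + ";"
    if isinstance(obj, LabelHierarchy):
        def render_cluster(level: int, members: list[str]) -> str:
            if len(members) == 1 and level >= obj.n_levels:
                return _newick_escape(members[0])
            if level >= obj.n_levels:
                inner = ",".join(_newick_escape(m) for m in members)
                return f"({inner})"
            groups: dict[int, list[str]] = {}
            for m in members:
                groups.setdefault(
                    obj.ancestor_at_level(m, level + 1), []
                ).append(m)
            if len(groups) == 1 and len(members) == 1:
                return _newick_escape(members[0])
            inner = ",".join(
                render_cluster(level + 1, g) + ":1"
                for _, g in sorted(groups.items())
            )
            return f"({inner})"

        return render_cluster(0, list(obj.leaf_labels)) + ";"
    raise TypeError(f"cannot export {type(obj).__name__} to Newick")
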