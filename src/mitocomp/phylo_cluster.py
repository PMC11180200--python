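"""Distance-based trees and RSCU clustering.

Two unsupervised views of the same species set:

* **Neighbor joining** (Saitou & Nei) on K2P distance matrices, with
  site-bootstrap support percentages on the internal bipartitions of the
  full-data tree. The agglomeration is deterministic: ties in the Q
  criterion are broken by the lexicographic order of the smallest leaf
  label in each cluster. Negative branch lengths are clamped to zero with
  the deficit moved to the sibling edge (the usual convention).

* **Agglomerative hierarchical clustering** of species × codon RSCU rows
  under Euclidean dissimilarity with single/complete/average/Ward linkage
  (Ward in the Ward.D2 sense: scipy's implementation on raw Euclidean
  inputs). The strength of the clustering structure is summarised by the
  agglomerative coefficient AC = mean_i (1 − h_first(i) / h_final), where
  h_first(i) is the height at which observation i first merges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage

from .divergence import AlignmentBlock, _pair_category_matrix, _pairwise_d

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "neighbor_joining",
    "k2p_matrix",
    "bootstrap_support",
    "ClusterDendrogram",
    "cluster_rscu",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if np.isnan(v).any():
            raise ValueError("distance matrix contains undefined (NaN) entries")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("matrix must be symmetric within 1e-12")


def _cat_matrix_to_distances(cats: np.ndarray, n: int) -> np.ndarray:
    d_flat = _pairwise_d(cats)
    out = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = d_flat[k]
            k += 1
    return out


def k2p_matrix(block: AlignmentBlock) -> DistanceMatrix:
    """All-pairs K2P distance matrix of an alignment (pairwise deletion)."""
    cats = _pair_category_matrix(block)
    values = _cat_matrix_to_distances(cats, len(block.records))
    return DistanceMatrix(labels=block.ids, values=values)


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0          # branch length to the parent
    support: float | None = None  # bootstrap percentage, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.length:.10g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        tag = ""
        if with_support and self.support is not None:
            tag = f"{self.support:.10g}"
        return f"({inner}){tag}:{self.length:.10g}"


@dataclass
class PhyloTree:
    """Unrooted tree rendered with a trifurcating root node."""

    root: TreeNode

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(leaf.label for leaf in self.root.leaves()))

    def to_newick(self, with_support: bool = True) -> str:
        inner = ",".join(c._newick(with_support) for c in self.root.children)
        return f"({inner});"

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions keyed by the leaf side not containing
        the lexicographically first label; values are the child nodes under
        the corresponding internal edge."""
        all_leaves = set(self.leaf_labels)
        ref = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}

        def visit(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.label}
            below = set()
            for child in node.children:
                below |= visit(child)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                out[frozenset(side)] = node
            return below

        visit(self.root)
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic (path-length) distances between all leaf pairs."""
        dists: dict[tuple[str, str], float] = {}

        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: node.length}
            per_child = [collect(c) for c in node.children]
            for i in range(len(per_child)):
                for j in range(i + 1, len(per_child)):
                    for la, da in per_child[i].items():
                        for lb, db in per_child[j].items():
                            key = (min(la, lb), max(la, lb))
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for sub in per_child:
                for label, dist in sub.items():
                    merged[label] = dist + node.length
            return merged

        collect(self.root)
        return dists


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic lexicographic tie-breaks."""
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # working copies; nodes indexed in parallel with D's rows
    D = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in matrix.labels]
    min_label: list[str] = list(matrix.labels)
    active: list[int] = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best_key = None
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                i, j = active[ai], active[aj]
                la, lb = sorted((min_label[i], min_label[j]))
                key = (q, la, lb)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (ai, aj)
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0.0:
            lj = dij
            li = 0.0
        elif lj < 0.0:
            li = dij
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to everything still active
        new_row = np.zeros(D.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        min_label.append(min(min_label[i], min_label[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # three-point closure
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


def bootstrap_support(
    block: AlignmentBlock,
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[PhyloTree, int]:
    """NJ tree with site-bootstrap support on its internal bipartitions.

    Columns are resampled with replacement; each replicate gets a K2P
    matrix and an NJ tree. Replicates with any undefined (saturated)
    distance are skipped and counted; support is the percentage of retained
    replicates containing each bipartition of the full-data tree. Returns
    ``(tree, n_skipped_replicates)``.
    """
    if len(block.records) < 4:
        raise ValueError("bootstrap support needs at least 4 sequences")
    cats = _pair_category_matrix(block)
    n_taxa = len(block.records)
    full_d = _cat_matrix_to_distances(cats, n_taxa)
    if np.isnan(full_d).any():
        raise ValueError(f"{block.locus}: full-data distance matrix has undefined entries")
    labels = block.ids
    tree = neighbor_joining(DistanceMatrix(labels, full_d))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    n_sites = cats.shape[1]
    skipped = 0
    used = 0
    for _ in range(reps):
        idx = rng.integers(0, n_sites, n_sites)
        d_rep = _cat_matrix_to_distances(cats[:, idx], n_taxa)
        if np.isnan(d_rep).any():
            skipped += 1
            continue
        rep_tree = neighbor_joining(DistanceMatrix(labels, d_rep))
        rep_bps = set(rep_tree.bipartitions())
        used += 1
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / used if used else math.nan
    return tree, skipped


@dataclass(frozen=True)
class ClusterDendrogram:
    labels: tuple[str, ...]
    method: str
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge table
    agglomerative_coefficient: float

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """The two label sets separated by the final merge."""
        assignment = fcluster(self.linkage_matrix, t=2, criterion="maxclust")
        one = frozenset(l for l, c in zip(self.labels, assignment) if c == 1)
        two = frozenset(l for l, c in zip(self.labels, assignment) if c == 2)
        return one, two


_LINKAGES = ("single", "complete", "average", "ward")


def _agglomerative_coefficient(Z: np.ndarray, n: int) -> float:
    h_final = Z[-1, 2]
    if h_final <= 0.0:
        return 0.0
    h_first = np.zeros(n)
    for merged_a, merged_b, height, _ in Z:
        for idx in (int(merged_a), int(merged_b)):
            if idx < n:
                h_first[idx] = height
    return float(np.mean(1.0 - h_first / h_final))


def cluster_rscu(matrix: pd.DataFrame, linkage: str = "ward") -> ClusterDendrogram:
    """Hierarchical agglomerative clustering of RSCU rows (Euclidean).

    ``matrix`` is a species × codon frame as produced by
    :func:`mitocomp.codon_usage.rscu_matrix`; rows are observations.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    labels = tuple(str(i) for i in matrix.index)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species ids in RSCU matrix")
    if len(labels) < 2:
        raise ValueError("clustering needs at least 2 observations")
    X = np.asarray(matrix.values, dtype=float)
    Z = _scipy_linkage(X, method=linkage, metric="euclidean")
    ac = _agglomerative_coefficient(Z, len(labels))
    return ClusterDendrogram(
        labels=labels,
        method=linkage,
        linkage_matrix=Z,
        agglomerative_coefficient=ac,
    )
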