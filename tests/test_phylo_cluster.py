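"""Neighbor joining, bootstrap support, and RSCU clustering."""

import numpy as np
import pandas as pd
import pytest

from mitocomp.divergence import AlignmentBlock
from mitocomp.io_formats import SequenceRecord
from mitocomp.phylo_cluster import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    cluster_rscu,
    k2p_matrix,
    neighbor_joining,
)
from mitocomp.synthetic_data import EvolveSimSpec, evolve_sequences, planted_rscu_matrix


def random_additive_tree(n, rng):
    """Random binary tree with positive branch lengths and its leaf-distance matrix."""
    leaves = [TreeNode(label=f"L{i:02d}", length=float(rng.uniform(0.1, 1.0))) for i in range(3)]
    root = TreeNode(children=list(leaves))
    parents = {id(l): root for l in leaves}
    for i in range(3, n):
        target = leaves[int(rng.integers(len(leaves)))]
        parent = parents[id(target)]
        inner = TreeNode(length=target.length / 2)
        target.length = target.length / 2
        parent.children.remove(target)
        parent.children.append(inner)
        new_leaf = TreeNode(label=f"L{i:02d}", length=float(rng.uniform(0.1, 1.0)))
        inner.children = [target, new_leaf]
        leaves.append(new_leaf)
        parents[id(target)] = inner
        parents[id(inner)] = parent
        parents[id(new_leaf)] = inner
    tree = PhyloTree(root)
    labels = sorted(tree.leaf_labels)
    ld = tree.leaf_distances()
    M = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            M[i, j] = M[j, i] = ld[(a, b)]
    return tree, DistanceMatrix(tuple(labels), M)


class TestDistanceMatrix:
    def test_asymmetric_matrix_rejected(self):
        M = np.array([[0.0, 1.0, 2.0], [1.1, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b", "c"), M)

    def test_k2p_matrix_from_alignment(self):
        recs = tuple(
            SequenceRecord(id=i, residues=s)
            for i, s in [("a", "AAAA"), ("b", "AAAG"), ("c", "AAAA")]
        )
        dm = k2p_matrix(AlignmentBlock(locus="x", records=recs))
        assert dm.values[0, 2] == 0.0
        assert dm.values[0, 1] > 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        """Branch lengths solve the three-point equations exactly."""
        M = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), M))
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_ultrametric_cherries_paired(self):
        labels = ("a", "b", "c", "d")
        M = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels, M))
        assert frozenset({"a", "b"}) in tree.bipartitions() or frozenset({"c", "d"}) in tree.bipartitions()

    def test_additive_matrices_recovered_exactly(self):
        """Topology and path lengths reproduced within 1e-9 on 8-leaf trees."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            true_tree, dm = random_additive_tree(8, rng)
            nj = neighbor_joining(dm)
            assert set(nj.bipartitions()) == set(true_tree.bipartitions())
            got = nj.leaf_distances()
            want = true_tree.leaf_distances()
            assert max(abs(got[k] - want[k]) for k in want) < 1e-9

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(33)
        _, dm = random_additive_tree(7, rng)
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            tuple(dm.labels[i] for i in perm), dm.values[np.ix_(perm, perm)]
        )
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
        assert set(t1.bipartitions()) == set(t2.bipartitions())
        d1, d2 = t1.leaf_distances(), t2.leaf_distances()
        assert all(abs(d1[k] - d2[k]) < 1e-9 for k in d1)

    def test_matches_independent_library_on_additive_input(self):
        """Cross-check against scikit-bio's NJ on the same matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(35)
        _, dm = random_additive_tree(8, rng)
        ours = neighbor_joining(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=list(dm.labels)))
        ref = skbio.TreeNode.read([ours.to_newick(with_support=False)])
        assert theirs.compare_rfd(ref) == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


class TestBootstrap:
    def _deep_split_block(self):
        rng = np.random.default_rng(41)
        root = "".join(rng.choice(list("ACGT"), 2000))
        spec = EvolveSimSpec(
            tree="((a:0.02,b:0.02):0.3,(c:0.02,d:0.02):0.3);",
            kappa=2.0,
            locus="deep",
        )
        return evolve_sequences(root, spec, mode="nucleotide", seed=43)

    def test_strong_bipartition_gets_high_support(self):
        tree, skipped = bootstrap_support(self._deep_split_block(), reps=200, seed=7)
        bps = tree.bipartitions()
        key = frozenset({"c", "d"})
        assert key in bps
        assert bps[key].support >= 95.0
        assert skipped == 0

    def test_supports_in_range_and_deterministic(self):
        block = self._deep_split_block()
        t1, _ = bootstrap_support(block, reps=50, seed=11)
        t2, _ = bootstrap_support(block, reps=50, seed=11)
        s1 = sorted(n.support for n in t1.bipartitions().values())
        s2 = sorted(n.support for n in t2.bipartitions().values())
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)


class TestClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"])
        dendro = cluster_rscu(df, "average")
        assert dendro.merge_heights[0] == 0.0
        one, two = dendro.top_split()
        assert {frozenset(one), frozenset(two)} == {
            frozenset({"a", "b"}), frozenset({"c"}),
        }

    def test_average_linkage_hand_example(self):
        """1-D points {0, 1, 10}: merges at 1 and 9.5, AC = 0.5965."""
        df = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        dendro = cluster_rscu(df, "average")
        assert dendro.merge_heights == pytest.approx([1.0, 9.5])
        assert dendro.agglomerative_coefficient == pytest.approx(0.5965, abs=5e-5)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average", "ward"])
    def test_heights_non_decreasing(self, linkage):
        rng = np.random.default_rng(51)
        df = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"s{i}" for i in range(12)])
        dendro = cluster_rscu(df, linkage)
        h = dendro.merge_heights
        assert (np.diff(h) >= -1e-12).all()
        assert 0.0 <= dendro.agglomerative_coefficient <= 1.0

    def test_ac_zero_when_all_merge_at_final_height(self):
        df = pd.DataFrame([[0.0], [1.0]], index=["a", "b"])
        assert cluster_rscu(df, "single").agglomerative_coefficient == 0.0

    def test_planted_two_clusters_recovered_at_top_split(self):
        matrix, labels = planted_rscu_matrix(
            n_species=10, n_clusters=2, effect_size=0.8, seed=3, noise=0.05
        )
        dendro = cluster_rscu(matrix, "ward")
        one, _ = dendro.top_split()
        planted = frozenset(matrix.index[i] for i in range(10) if labels[i] == 0)
        other = frozenset(matrix.index) - planted
        assert frozenset(one) in (planted, other)

    def test_ward_ac_tends_to_dominate_average_on_clustered_data(self):
        """On strongly clustered RSCU data Ward shows the strongest
        structure, as agglomerative-coefficient comparisons typically do."""
        wins = 0
        for seed in range(10):
            matrix, _ = planted_rscu_matrix(
                n_species=12, n_clusters=3, effect_size=0.8, seed=seed, noise=0.05
            )
            ac_ward = cluster_rscu(matrix, "ward").agglomerative_coefficient
            ac_avg = cluster_rscu(matrix, "average").agglomerative_coefficient
            wins += ac_ward >= ac_avg
        assert wins >= 8

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[0.0], [1.0]], index=["a", "a"])
        with pytest.raises(ValueError):
            cluster_rscu(df)
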