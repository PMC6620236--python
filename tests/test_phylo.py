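"""Alignment, column filtering, NJ trees and GRE clade assignment."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from bmcscan.model import BmcscanError
from bmcscan.phylo import (
    MSA,
    assign_function,
    classify_gre,
    filter_columns,
    midpoint_root,
    nj_tree,
    poisson_distance_matrix,
    progressive_align,
)
from bmcscan.simulate import mutate, random_protein


def random_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths; returns (tree, ids)."""
    ids = [f"L{i}" for i in range(n_leaves)]
    nodes = [TreeNode(name=i) for i in ids]
    for node in nodes:
        node.length = round(float(rng.uniform(0.1, 2.0)), 3)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(children=[nodes.pop(j), nodes.pop(i)])
        parent.length = round(float(rng.uniform(0.1, 2.0)), 3)
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root, ids


def tree_distances(tree, ids):
    n = len(ids)
    dm = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = tips[ids[i]].distance(tips[ids[j]])
    return dm


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        msa = progressive_align([("a", "MKVLAW"), ("b", "MKVLAW")])
        assert msa.rows == ["MKVLAW", "MKVLAW"]

    def test_single_gap_column(self):
        # verified against an exhaustive pairwise alignment by hand: the
        # only optimal global alignment puts D against a gap
        msa = progressive_align([("a", "ACDEF"), ("b", "ACEF")])
        assert msa.rows == ["ACDEF", "AC-EF"]

    def test_alignment_at_least_as_long_as_longest_input(self):
        rng = np.random.default_rng(3)
        seqs = [(f"s{i}", random_protein(rng, int(rng.integers(20, 60)))) for i in range(5)]
        msa = progressive_align(seqs)
        assert msa.length >= max(len(s) for _, s in seqs)
        for sid, seq in seqs:
            assert msa.ungapped(sid) == seq  # ungapping recovers the input

    def test_fewer_than_two_sequences_is_an_error(self):
        with pytest.raises(BmcscanError):
            progressive_align([("a", "MKVLA")])


class TestFilterColumns:
    def test_conserved_tryptophan_column_kept(self):
        msa = MSA(ids=["a", "b"], rows=["W", "W"])
        assert filter_columns(msa).length == 1

    def test_gap_heavy_discordant_column_removed(self):
        # column 1: half gaps (−4 each) + discordant residues; mean vs best
        # consensus is negative => removed.  Column 2 anchors the alignment.
        msa = MSA(ids=list("abcd"), rows=["-W", "-W", "KW", "DW"])
        filtered = filter_columns(msa)
        assert filtered.rows == ["W", "W", "W", "W"]

    def test_identical_sequence_msa_loses_nothing(self):
        msa = MSA(ids=["a", "b", "c"], rows=["MKVLAW"] * 3)
        assert filter_columns(msa).rows == msa.rows

    def test_all_columns_removed_is_an_error(self):
        msa = MSA(ids=list("abcd"), rows=["-K", "-D", "K-", "D-"])
        with pytest.raises(BmcscanError):
            filter_columns(msa)


class TestNJ:
    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            tree, ids = random_tree(rng, int(rng.integers(5, 9)))
            dm = tree_distances(tree, ids)
            rebuilt = nj_tree(dm, ids)
            dm2 = tree_distances(rebuilt, ids)
            assert np.allclose(dm, dm2, atol=1e-8)

    def test_three_leaf_closed_form(self):
        # d(a,b)=3, d(a,c)=5, d(b,c)=6 => a=1, b=2, c=4
        dm = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = nj_tree(dm, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_non_symmetric_matrix_is_an_error(self):
        with pytest.raises(BmcscanError):
            nj_tree(np.array([[0, 1], [2, 0]], float), ["a", "b"])

    def test_two_leaf_midpoint_halves_the_path(self):
        tree = TreeNode.read(io.StringIO("(a:1,b:3);"))
        rooted = midpoint_root(tree)
        depths = {t.name: t.distance(rooted.root()) for t in rooted.tips()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_midpoint_bisects_diameter(self):
        rng = np.random.default_rng(29)
        tree, ids = random_tree(rng, 7)
        dm = tree_distances(tree, ids)
        rooted = midpoint_root(nj_tree(dm, ids))
        diameter = dm.max()
        depths = [t.distance(rooted.root()) for t in rooted.tips()]
        assert max(depths) == pytest.approx(diameter / 2)


class TestAssignFunction:
    def _tree(self):
        return TreeNode.read(
            io.StringIO("(((r1:0.1,r2:0.1):0.1,q:0.15):0.5,(s1:0.1,s2:0.1):0.5);")
        )

    def test_query_inside_pure_clade_takes_its_label(self):
        labels = {"r1": "CutC", "r2": "CutC", "s1": "PduC", "s2": "PduC"}
        assert assign_function(self._tree(), labels, "q") == "CutC"

    def test_equidistant_between_two_clades_is_unclassified(self):
        tree = TreeNode.read(io.StringIO("((a:1,b:1):1,q:1);"))
        labels = {"a": "X", "b": "Y"}
        assert assign_function(tree, labels, "q") == "unclassified"

    def test_invariant_to_leaf_order(self):
        labels = {"r1": "CutC", "r2": "CutC", "s1": "PduC", "s2": "PduC"}
        mirrored = TreeNode.read(
            io.StringIO("((s2:0.1,s1:0.1):0.5,((r2:0.1,r1:0.1):0.1,q:0.15):0.5);")
        )
        assert assign_function(mirrored, labels, "q") == "CutC"

    def test_no_labels_is_an_error(self):
        with pytest.raises(BmcscanError):
            assign_function(self._tree(), {}, "q")


class TestGreClassification:
    def test_held_out_family_members_are_recovered(self, bundle):
        from bmcscan.model import GRE_FAMILIES

        rng = np.random.default_rng(41)
        fam_ref = {
            g.family: g.sequence
            for g in bundle.gre_references
            if g.family in GRE_FAMILIES
        }
        queries, expected = [], []
        for i in range(12):
            fam = GRE_FAMILIES[i % len(GRE_FAMILIES)]
            queries.append((f"q{i}", mutate(fam_ref[fam], 0.10, rng)))
            expected.append(fam)
        labels = classify_gre(bundle, queries)
        correct = sum(labels[f"q{i}"] == expected[i] for i in range(12))
        assert correct >= 11
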