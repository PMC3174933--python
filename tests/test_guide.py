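import itertools
import random

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from orfalign import (
    DistanceTable,
    InputError,
    NucSeq,
    build_guide_tree,
    kmer_distance_matrix,
)


def test_identical_sequences_have_zero_distance():
    seqs = [NucSeq("a", "ATGATGATG"), NucSeq("b", "ATGATGATG")]
    d = kmer_distance_matrix(seqs, k=3)
    assert d.get("a", "b") == 0.0


def test_disjoint_kmer_sets_have_distance_one():
    seqs = [NucSeq("a", "AAAAAA"), NucSeq("b", "CCCCCC")]
    assert kmer_distance_matrix(seqs, k=3).get("a", "b") == 1.0


def test_kmer_distance_hand_enumeration():
    # 3-mers: {ATG, TGA, GAT} vs {ATG, TGC, GCC, CCC}; shared {ATG};
    # min repertoire 3 -> distance 1 - 1/3
    seqs = [NucSeq("a", "ATGATG"), NucSeq("b", "ATGCCC")]
    assert kmer_distance_matrix(seqs, k=3).get("a", "b") == pytest.approx(1 - 1 / 3)


def test_short_sequence_warns_and_gets_distance_one():
    seqs = [NucSeq("a", "ATG"), NucSeq("b", "ATGATGATG")]
    with pytest.warns(UserWarning, match="shorter than k"):
        d = kmer_distance_matrix(seqs, k=6)
    assert d.get("a", "b") == 1.0


def test_upgma_two_ids_is_a_cherry():
    t = build_guide_tree(DistanceTable(("a", "b"), np.array([[0, 0.4], [0.4, 0]])))
    assert sorted(t.leaf_ids()) == ["a", "b"]
    assert t.root.height == pytest.approx(0.2)


def test_upgma_three_ids_forced_topology():
    ids = ("A", "B", "C")
    v = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
    t = build_guide_tree(DistanceTable(ids, v))
    clades = {frozenset(n.leaf_ids()) for n in t.root.postorder()}
    assert frozenset({"A", "B"}) in clades


def test_upgma_matches_scipy_average_linkage():
    """Cophenetic distances equal scipy's UPGMA on random tie-free tables."""
    rng = random.Random(23)
    for _ in range(10):
        n = rng.randint(3, 7)
        ids = tuple(f"t{i}" for i in range(n))
        cond = np.array([rng.uniform(0.1, 1.0) for _ in range(n * (n - 1) // 2)])
        mat = squareform(cond)
        tree = build_guide_tree(DistanceTable(ids, mat))
        heights = {}
        for node in tree.root.postorder():
            if not node.is_leaf:
                left, right = node.children
                for a in left.leaf_ids():
                    for b in right.leaf_ids():
                        heights[frozenset((a, b))] = 2 * node.height
        ours = np.array(
            [heights[frozenset((a, b))] for a, b in itertools.combinations(ids, 2)]
        )
        theirs = cophenet(linkage(cond, method="average"))
        assert np.allclose(ours, theirs)


def test_upgma_deterministic_under_ties():
    # all distances equal: the lexicographically smallest pair merges first
    ids = ("d", "b", "c", "a")
    v = np.ones((4, 4)) - np.eye(4)
    t = build_guide_tree(DistanceTable(ids, v))
    first = min(
        (n for n in t.root.postorder() if not n.is_leaf), key=lambda n: n.height
    )
    assert sorted(first.leaf_ids()) == ["a", "b"]


def test_guide_tree_needs_two_ids():
    with pytest.raises(InputError):
        build_guide_tree(DistanceTable(("a",), np.zeros((1, 1))))


def test_newick_export_parses():
    import io as _io

    from Bio import Phylo

    ids = ("a", "b", "c")
    v = np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]])
    t = build_guide_tree(DistanceTable(ids, v))
    tree = Phylo.read(_io.StringIO(t.newick()), "newick")
    assert sorted(x.name for x in tree.get_terminals()) == ["a", "b", "c"]
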