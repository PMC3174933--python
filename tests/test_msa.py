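import random

import pytest

from orfalign import (
    InputError,
    MultipleAlignment,
    NucSeq,
    ParameterError,
    align_alignments,
    align_pair,
    align_sequence_to_alignment,
    align_sequences,
    build_guide_tree,
    kmer_distance_matrix,
    oracle_align,
    progressive_align,
    refine_2cut,
    retree_from_sp,
    sp_score,
)
from conftest import NONSTOP_CODONS

CODON_MOVES = tuple((da, db) for da in (0, 3) for db in (0, 3) if (da, db) != (0, 0))
SEQ_VS_COLUMN_MOVES = tuple(
    (da, db) for da in (0, 3) for db in range(4) if (da, db) != (0, 0)
)


def _family(rng, n_seqs, n_codons, sub=0.1):
    base = [rng.choice(NONSTOP_CODONS) for _ in range(n_codons)]
    seqs = []
    for i in range(n_seqs):
        codons = [
            rng.choice(NONSTOP_CODONS) if rng.random() < sub else c for c in base
        ]
        seqs.append(NucSeq(f"s{i}", "".join(codons)))
    return seqs


def test_sp_of_identical_single_codon_rows(scheme):
    A1 = MultipleAlignment.from_seq(NucSeq("x", "TGG"))
    A2 = MultipleAlignment.from_seq(NucSeq("y", "TGG"))
    m = align_alignments(A1, A2, scheme)
    assert sp_score(m, scheme) == 11
    m3 = align_sequence_to_alignment(NucSeq("z", "TGG"), m, scheme)
    assert sp_score(m3, scheme) == 3 * 11
    assert m3.ncols == 1


def test_two_row_sp_equals_pair_score(rng, scheme):
    for _ in range(10):
        a = NucSeq("a", "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 30))))
        b = NucSeq("b", "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 30))))
        pa = align_pair(a, b, scheme)
        assert sp_score(pa.to_msa(), scheme) == pa.score


def test_align_alignments_single_rows_match_codon_unit_oracle(rng, scheme):
    """Merging two 1-row blocks equals the pairwise optimum restricted to
    codon-unit moves (columns are atomic on both sides)."""
    for _ in range(15):
        a = NucSeq("a", "".join(rng.choice(NONSTOP_CODONS) for _ in range(rng.randint(1, 4))))
        b = NucSeq("b", "".join(rng.choice(NONSTOP_CODONS) for _ in range(rng.randint(1, 4))))
        merged = align_alignments(
            MultipleAlignment.from_seq(a), MultipleAlignment.from_seq(b), scheme
        )
        expected, _ = oracle_align(a, b, scheme, moves=CODON_MOVES)
        assert sp_score(merged, scheme) == expected


def test_leaf_merge_matches_seven_move_oracle(rng, scheme):
    """A leaf merged into a gap-free 1-row block equals the pairwise
    optimum where only the leaf may be re-framed."""
    for _ in range(15):
        block_seq = NucSeq(
            "blk", "".join(rng.choice(NONSTOP_CODONS) for _ in range(rng.randint(1, 4)))
        )
        s = NucSeq("s", "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 10))))
        merged = align_sequence_to_alignment(
            s, MultipleAlignment.from_seq(block_seq), scheme
        )
        expected, _ = oracle_align(block_seq, s, scheme, moves=SEQ_VS_COLUMN_MOVES)
        assert sp_score(merged, scheme) == expected


def test_merges_preserve_induced_subalignments(rng, scheme):
    seqs = _family(rng, 5, 12)
    tree = build_guide_tree(kmer_distance_matrix(seqs, k=4))
    A = progressive_align(seqs, tree, scheme)
    left = A.subset(["s0", "s1"])
    right = A.subset(["s2", "s3", "s4"])
    merged = align_alignments(left, right, scheme)
    for sub in (left, right):
        for x in sub.ids:
            for y in sub.ids:
                if x < y:
                    assert merged.induced_pair(x, y) == sub.induced_pair(x, y)


def test_progressive_two_sequences_equals_align_pair(rng, scheme):
    a = NucSeq("a", "ATTTCGAAATG")
    b = NucSeq("b", "ATCGAGATG")
    tree = build_guide_tree(kmer_distance_matrix([a, b], k=3))
    A = progressive_align([a, b], tree, scheme)
    assert sp_score(A, scheme) == align_pair(a, b, scheme).score


@pytest.mark.parametrize("n", [3, 8, 20])
def test_progressive_identical_orfs_gap_free(n, scheme):
    seqs = [NucSeq(f"s{i}", "ATGGCCTTTAAACCC") for i in range(n)]
    tree = build_guide_tree(kmer_distance_matrix(seqs, k=4))
    A = progressive_align(seqs, tree, scheme)
    assert A.ncols == 5
    assert all(A.nt_row(i) == "ATGGCCTTTAAACCC" for i in A.ids)
    assert A.events() == []
    assert sp_score(A, scheme) == n * (n - 1) // 2 * align_pair(
        seqs[0], NucSeq("q", seqs[0].residues), scheme
    ).score


def test_progressive_places_injected_frameshift(rng, scheme):
    seqs = _family(rng, 4, 12, sub=0.05)
    mutated = seqs[2].residues[:16] + seqs[2].residues[17:]  # 1-nt deletion
    seqs[2] = NucSeq("s2", mutated, "lowpen")
    tree = build_guide_tree(kmer_distance_matrix(seqs, k=4))
    A = progressive_align(seqs, tree, scheme)
    assert any("!" in s for s in A.rows["s2"])
    for s in seqs:
        assert A.ungapped(s.id) == s.residues


def test_structural_invariants_of_output(rng, scheme):
    seqs = _family(rng, 6, 10)
    res = align_sequences(seqs, scheme)
    A = res.alignment
    for c in range(A.ncols):
        assert any(A.rows[i][c] != "---" for i in A.ids)
    assert A.ncols >= max((len(s.residues) + 2) // 3 for s in seqs)
    for s in seqs:
        assert A.ungapped(s.id) == s.residues


def test_refine_already_optimal_two_rows_unchanged(scheme):
    a, b = NucSeq("a", "ATGGCCTTT"), NucSeq("b", "ATGGCGTTT")
    pa = align_pair(a, b, scheme).to_msa()
    tree = build_guide_tree(kmer_distance_matrix([a, b], k=3))
    refined = refine_2cut(pa, tree, scheme)
    assert refined.rows == pa.rows


def test_refine_improves_corrupted_alignment(rng, scheme):
    seqs = _family(rng, 5, 10)
    res = align_sequences(seqs, scheme)
    A = res.alignment
    # corrupt: insert a gap site mid-row, pad every other row at the end
    rows = {i: list(A.rows[i]) for i in A.ids}
    victim = A.ids[2]
    rows[victim].insert(3, "---")
    for i in A.ids:
        if i != victim:
            rows[i].append("---")
    corrupted = MultipleAlignment(A.ids, rows, A.set_labels, A.codes, validate=False)
    base_sp = sp_score(corrupted, scheme)
    tree = build_guide_tree(kmer_distance_matrix(seqs, k=4))
    traj = []
    refined = refine_2cut(corrupted, tree, scheme, trajectory=traj)
    assert sp_score(refined, scheme) >= base_sp
    assert traj == sorted(traj)


def test_refine_rejects_negative_max_iter(scheme):
    a, b = NucSeq("a", "ATG"), NucSeq("b", "ATG")
    A = align_pair(a, b, scheme).to_msa()
    tree = build_guide_tree(kmer_distance_matrix([a, b], k=2))
    with pytest.raises(ParameterError):
        refine_2cut(A, tree, scheme, max_iter=-1)


def test_retree_identical_rows_form_zero_cherry(scheme):
    seqs = [
        NucSeq("a", "ATGGCCTTTAAA"),
        NucSeq("b", "ATGGCCTTTAAA"),
        NucSeq("c", "TGGTGGTGGTGG"),
    ]
    res = align_sequences(seqs, scheme)
    t = retree_from_sp(res.alignment, scheme)
    clades = {frozenset(n.leaf_ids()) for n in t.root.postorder()}
    assert frozenset({"a", "b"}) in clades


def test_align_alignments_rejects_overlapping_ids(scheme):
    A = MultipleAlignment.from_seq(NucSeq("x", "ATG"))
    with pytest.raises(InputError):
        align_alignments(A, A, scheme)
    with pytest.raises(InputError):
        align_sequence_to_alignment(NucSeq("x", "ATG"), A, scheme)
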