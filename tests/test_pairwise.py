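import random

import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from orfalign import (
    InputError,
    NucSeq,
    RowInfo,
    ScoringScheme,
    align_pair,
    enumerate_moves,
    oracle_align,
    score_induced_pair,
    translate_raw,
)
from conftest import NONSTOP_CODONS, random_scheme


def test_move_set():
    moves = enumerate_moves()
    assert len(moves) == 15
    assert sum(1 for m in moves if m.frameshifts == 0) == 3
    assert sum(1 for m in moves if m.frameshifts > 0) == 12
    assert {(m.da, m.db) for m in moves if m.frameshifts == 0} == {
        (3, 3),
        (3, 0),
        (0, 3),
    }


def test_move_templates():
    from orfalign import Move

    assert Move(3, 0).site_template("b") == "---"
    assert Move(1, 3).site_template("a") == "!!n"
    assert Move(2, 3).site_template("a") == "!nn"
    with pytest.raises(InputError):
        Move(0, 0)


WORKED_EXAMPLE_SCORE = 3  # fixed by the brute-force oracle before the DP build


def test_worked_example(scheme):
    a, b = NucSeq("s1", "ATTTCGAAATG"), NucSeq("s2", "ATCGAGATG")
    pa = align_pair(a, b, scheme)
    assert pa.score == WORKED_EXAMPLE_SCORE
    assert pa.score == oracle_align(a, b, scheme)[0]


def test_identity_orf_alignment(scheme):
    a = NucSeq("a", "ATGGCCTTT")
    b = NucSeq("b", "ATGGCCTTT")
    pa = align_pair(a, b, scheme)
    assert pa.score == 5 + 4 + 6  # M/M + A/A + F/F
    assert pa.sites_a == ("ATG", "GCC", "TTT")
    assert pa.events == ()


def test_single_extra_nucleotide_gives_one_frameshift(scheme):
    pa = align_pair(NucSeq("a", "ATGTTT"), NucSeq("b", "ATGATTT"), scheme)
    fs = [e for e in pa.events if e.event_type == "frameshift"]
    assert len(fs) == 1
    assert pa.score == oracle_align("ATGTTT", "ATGATTT", scheme)[0]


def test_oracle_equivalence_random_pairs(rng):
    """DP == brute-force oracle on random short pairs and random penalties."""
    for _ in range(150):
        a = NucSeq("a", "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8))))
        b = NucSeq("b", "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8))))
        sch = random_scheme(rng)
        assert align_pair(a, b, sch).score == oracle_align(a, b, sch)[0]


def test_roundtrip_and_score_consistency(rng, scheme):
    for _ in range(40):
        a = NucSeq("a", "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 40))))
        b = NucSeq("b", "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 40))))
        pa = align_pair(a, b, scheme)
        assert "".join(pa.sites_a).replace("-", "").replace("!", "") == a.residues
        assert "".join(pa.sites_b).replace("-", "").replace("!", "") == b.residues
        assert not any(
            x == "---" and y == "---" for x, y in zip(pa.sites_a, pa.sites_b)
        )
        assert pa.score == score_induced_pair(
            pa.sites_a, pa.sites_b, RowInfo(), RowInfo(), scheme
        )


def test_needleman_wunsch_reduction(rng):
    """With the frameshift move priced out, the coding-aware DP equals a
    classical semi-global amino-acid aligner on in-frame, stop-free ORFs."""
    sch = ScoringScheme(fs=-(10**6))
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = sch.gap_open + sch.gap_ext
    al.extend_gap_score = sch.gap_ext
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    al.mode = "global"
    for _ in range(30):
        a = "".join(rng.choice(NONSTOP_CODONS) for _ in range(rng.randint(2, 12)))
        b = "".join(rng.choice(NONSTOP_CODONS) for _ in range(rng.randint(2, 12)))
        ours = align_pair(NucSeq("a", a), NucSeq("b", b), sch).score
        theirs = al.score(translate_raw(a), translate_raw(b))
        assert ours == theirs


def test_per_row_penalty_sets():
    sch = ScoringScheme(fs_lowpen=-2, stop_lowpen=-1)
    a = NucSeq("a", "ATGAAATTT")
    b = NucSeq("b", "ATGAAAATTT", set_label="lowpen")  # one extra nucleotide
    pa = align_pair(a, b, sch)
    # the cheap lowpen frameshift makes the event worth placing in b
    assert any(e.seq_id == "b" and e.event_type == "frameshift" for e in pa.events)
    assert pa.score == oracle_align(a, b, sch)[0]


def test_align_pair_input_validation(scheme):
    with pytest.raises(InputError):
        align_pair("ATG", NucSeq("b", "ATG"), scheme)
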