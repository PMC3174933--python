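import random

import pytest

from orfalign import (
    ConfigError,
    InvalidColumnError,
    RowInfo,
    ScoringScheme,
    classify_site,
    score_induced_pair,
    site_score,
)
from conftest import NONSTOP_CODONS


def test_site_score_examples(scheme):
    # W/W diagonal, frameshift facing a codon, stop facing a frameshift
    assert site_score("TGG", "TGG", scheme=scheme) == 11
    assert site_score("A!G", "ATG", scheme=scheme) == -30
    assert site_score("TGA", "!AG", scheme=scheme) == -130


def test_site_score_symmetry(scheme):
    rng = random.Random(5)
    sites = ["TGG", "A!G", "!!T", "TGA", "---", "ATN"]
    for _ in range(100):
        a, b = rng.choice(sites), rng.choice(sites)
        if a == "---" and b == "---":
            continue
        la = rng.choice(["reliable", "lowpen"])
        lb = rng.choice(["reliable", "lowpen"])
        assert site_score(a, b, la, lb, scheme) == site_score(b, a, lb, la, scheme)


def test_full_nonstop_reduces_to_matrix(scheme):
    rng = random.Random(6)
    for _ in range(50):
        a, b = rng.choice(NONSTOP_CODONS), rng.choice(NONSTOP_CODONS)
        from orfalign import translate_raw

        assert site_score(a, b, scheme=scheme) == scheme.sub(
            translate_raw(a), translate_raw(b)
        )


def test_gap_side_contributes_gap_ext(scheme):
    assert site_score("TGG", "---", scheme=scheme) == scheme.gap_ext
    with pytest.raises(InvalidColumnError):
        site_score("---", "---", scheme=scheme)


def test_lowpen_set_uses_soft_penalties():
    sch = ScoringScheme(fs_lowpen=-20, stop_lowpen=-10)
    assert site_score("A!G", "ATG", "lowpen", "reliable", sch) == -20
    assert site_score("A!G", "ATG", "reliable", "lowpen", sch) == -30
    assert site_score("TGA", "ATG", "lowpen", "reliable", sch) == -10


def test_terminal_flags_lift_event_penalties(scheme):
    assert site_score("TGA", "ATG", scheme=scheme, a_terminal=True) == 0
    assert site_score("TGA", "ATG", scheme=scheme) == -100


def test_positive_penalties_rejected():
    with pytest.raises(ConfigError):
        ScoringScheme(gap_open=1)
    with pytest.raises(ConfigError):
        ScoringScheme(fs=5)


def test_matrix_is_symmetric(scheme):
    assert (scheme.matrix == scheme.matrix.T).all()


def test_classify_site_rejects_mixed_cells():
    for bad in ("A-G", "!-G", "AT", "ATGC", "A!-"):
        with pytest.raises(InvalidColumnError):
            classify_site(bad)


def test_natural_scorer_run_level_gaps(scheme):
    info = RowInfo()
    # internal 2-site gap run: open + 2*ext; terminal runs free
    a = ["ATG", "---", "---", "TGG"]
    b = ["ATG", "AAA", "CCC", "TGG"]
    got = score_induced_pair(a, b, info, info, scheme)
    assert got == scheme.sub("M", "M") + scheme.sub("W", "W") + scheme.gap_open + 2 * scheme.gap_ext
    # leading gap run is free
    a2 = ["---", "AAA", "TGG"]
    b2 = ["ATG", "AAA", "TGG"]
    assert score_induced_pair(a2, b2, info, info, scheme) == scheme.sub(
        "K", "K"
    ) + scheme.sub("W", "W")


def test_forced_tail_is_free_but_internal_fs_is_not(scheme):
    info = RowInfo()
    # row a ungaps to 8 nt: tail chunk of length 2 == 8 % 3 -> free
    a = ["ATG", "AAA", "!TG"]
    b = ["ATG", "AAA", "TTG"]
    assert score_induced_pair(a, b, info, info, scheme) == scheme.sub(
        "M", "M"
    ) + scheme.sub("K", "K")
    # same shape but the row continues afterwards: the fs is a real event
    a2 = ["ATG", "!TG", "AAA"]
    b2 = ["ATG", "TTG", "AAA"]
    assert score_induced_pair(a2, b2, info, info, scheme) == scheme.sub(
        "M", "M"
    ) + scheme.sub("K", "K") + scheme.fs
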