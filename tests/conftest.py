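import random

import pytest

from orfalign import NucSeq, ScoringScheme

NONSTOP_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if (a + b + c) not in ("TAA", "TAG", "TGA")
)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture
def make_orf():
    """Random stop-free in-frame ORF factory."""

    def _make(n_codons, rng, sid="s"):
        return NucSeq(
            sid, "".join(rng.choice(NONSTOP_CODONS) for _ in range(n_codons))
        )

    return _make


@pytest.fixture
def rng():
    return random.Random(20240917)


def random_scheme(rng):
    """Random admissible penalty draw (shared by oracle-equivalence tests)."""
    return ScoringScheme(
        gap_open=-rng.randint(0, 9),
        gap_ext=-rng.randint(0, 3),
        fs=-rng.randint(0, 40),
        stop=-rng.randint(0, 100),
    )
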