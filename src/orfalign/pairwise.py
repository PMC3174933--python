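"""Frameshift-aware pairwise alignment of two coding nucleotide sequences.

The recursion generalises the three-move Needleman-Wunsch/Gotoh scheme: a
cell ``(i, j)`` of the nucleotide-prefix table is reached from the 4x4
square of cells consuming 0-3 nucleotides from each sequence, i.e. 15
moves.  Three of them (codon substitution, codon insertion, codon
deletion) are the classical amino-acid moves; the other 12 consume 1 or 2
nucleotides on at least one side and therefore induce frameshifts, padded
to codon sites with ``!``.  Affine gaps use three state tables (match,
deletion, insertion); terminal gaps, terminal stops and terminal partial
codons are free (semi-global convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _dp
from .codes import GeneticCode
from .errors import InputError
from .model import EventRecord, GAP_SITE, NucSeq, PairwiseAlignment, pad_chunk, _row_events
from .scoring import RowInfo, ScoringScheme, score_induced_pair

__all__ = ["Move", "enumerate_moves", "align_pair"]


@dataclass(frozen=True)
class Move:
    """One admissible DP move: ``da``/``db`` nucleotides consumed from each
    sequence (0 = a gap site on that side)."""

    da: int
    db: int

    def __post_init__(self) -> None:
        if not (0 <= self.da <= 3 and 0 <= self.db <= 3) or (self.da, self.db) == (0, 0):
            raise InputError(f"inadmissible move ({self.da},{self.db})")

    @property
    def frameshifts_a(self) -> int:
        return 1 if self.da in (1, 2) else 0

    @property
    def frameshifts_b(self) -> int:
        return 1 if self.db in (1, 2) else 0

    @property
    def frameshifts(self) -> int:
        return self.frameshifts_a + self.frameshifts_b

    def site_template(self, side: str = "a") -> str:
        """Schematic site produced on one side (``n`` = consumed nucleotide)."""
        d = self.da if side == "a" else self.db
        return GAP_SITE if d == 0 else "!" * (3 - d) + "n" * d


def enumerate_moves() -> list[Move]:
    """All 15 admissible moves of the pairwise recursion."""
    return [
        Move(da, db)
        for da in range(4)
        for db in range(4)
        if (da, db) != (0, 0)
    ]


def _codon_arrays(residues: str, code: GeneticCode, scheme: ScoringScheme):
    n = len(residues)
    aa = np.zeros(n + 1, dtype=np.int64)
    stop = np.zeros(n + 1, dtype=np.bool_)
    for i in range(3, n + 1):
        codon = residues[i - 3 : i]
        sym = code.translate_codon(codon)
        stop[i] = sym == "*"
        aa[i] = scheme.aa_index(sym)
    return aa, stop


def align_pair(
    a: NucSeq,
    b: NucSeq,
    scheme: ScoringScheme | None = None,
    codes: Mapping[str, GeneticCode] | None = None,
) -> PairwiseAlignment:
    """Maximum-score frameshift-aware alignment of two sequences.

    ``codes`` optionally overrides each sequence's genetic code by id.  The
    reported score is recomputed from the returned columns with the natural
    scorer, guaranteeing score/alignment consistency.
    """
    scheme = scheme or ScoringScheme()
    if not isinstance(a, NucSeq) or not isinstance(b, NucSeq):
        raise InputError("align_pair expects NucSeq inputs")
    code_a = (codes or {}).get(a.id, a.code)
    code_b = (codes or {}).get(b.id, b.code)
    ra, rb = a.residues, b.residues
    n, m = len(ra), len(rb)
    aaA, stopA = _codon_arrays(ra, code_a, scheme)
    aaB, stopB = _codon_arrays(rb, code_b, scheme)
    M, D, I, ps, pm = _dp.pair_dp(
        n,
        m,
        aaA,
        stopA,
        aaB,
        stopB,
        scheme.matrix,
        np.int64(scheme.gap_open),
        np.int64(scheme.gap_ext),
        np.int64(scheme.fs_for(a.set_label)),
        np.int64(scheme.fs_for(b.set_label)),
        np.int64(scheme.stop_for(a.set_label)),
        np.int64(scheme.stop_for(b.set_label)),
    )
    finals = (M[n, m], D[n, m], I[n, m])
    state = int(np.argmax(finals))  # ties: M > D > I by argmax order
    dp_score = int(finals[state])
    sites_a: list[str] = []
    sites_b: list[str] = []
    i, j = n, m
    while (i, j) != (0, 0):
        mv = int(pm[state, i, j])
        prev = int(ps[state, i, j])
        da, db = mv // 4, mv % 4
        sites_a.append(GAP_SITE if da == 0 else pad_chunk(ra[i - da : i]))
        sites_b.append(GAP_SITE if db == 0 else pad_chunk(rb[j - db : j]))
        i, j, state = i - da, j - db, prev
    sites_a.reverse()
    sites_b.reverse()
    natural = score_induced_pair(
        sites_a,
        sites_b,
        RowInfo(a.set_label, code_a),
        RowInfo(b.set_label, code_b),
        scheme,
    )
    if natural != dp_score:  # pragma: no cover - internal consistency guard
        raise RuntimeError(
            f"DP score {dp_score} != recomputed score {natural} for "
            f"{a.id!r} vs {b.id!r}"
        )
    events: list[EventRecord] = []
    events.extend(_row_events(a.id, sites_a, code_a))
    events.extend(_row_events(b.id, sites_b, code_b))
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        sites_a=tuple(sites_a),
        sites_b=tuple(sites_b),
        score=dp_score,
        events=tuple(events),
    )
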