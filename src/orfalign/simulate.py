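"""Synthetic coding-sequence families with known ground truth.

A random stop-free ancestor ORF (starting ATG) evolves along a star
topology: each derived lineage draws independent codon substitutions
(uniform over non-stop codons) and optional codon indels.  On top of that,
explicit 1-2 nt deletions (frameshifts) and premature stop codons are
injected at stated positions and recorded as truth, emulating pseudogene
decay and sequencing-error scenarios.  The star topology keeps the true
per-sequence alignment to the ancestor trivial to track; no attempt is
made at realistic codon models (dN/dS, rate heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .codes import GeneticCode, STANDARD_CODE
from .errors import ParameterError
from .model import NucSeq

__all__ = [
    "EvolutionParams",
    "TruthRecord",
    "evolve_orf",
    "inject_frameshift",
    "inject_stop",
]

_NONSTOP = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if STANDARD_CODE.codon_map[a + b + c] != "*"
)


@dataclass(frozen=True)
class EvolutionParams:
    """Star-topology simulation settings.

    ``frameshift_injections`` is a list of ``(seq_index, codon_pos,
    del_len)`` with 1-based codon positions in the mutated sequence;
    ``stop_injections`` is a list of ``(seq_index, codon_index)`` (1-based,
    internal).  Defaults mirror a small pseudogene-family scenario: 5
    sequences of 100 codons at 5% codon substitution probability per
    lineage.
    """

    n_codons: int = 100
    n_seqs: int = 5
    sub_prob: float = 0.05
    indel_prob: float = 0.0
    frameshift_injections: tuple[tuple[int, int, int], ...] = ()
    stop_injections: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sub_prob <= 1 and 0 <= self.indel_prob <= 1):
            raise ParameterError("probabilities must lie in [0, 1]")
        if self.n_codons < 2 or self.n_seqs < 1:
            raise ParameterError("need >= 2 codons and >= 1 sequence")


@dataclass
class TruthRecord:
    """Ground truth of one simulated family."""

    ancestor: str
    events: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    # per sequence: list over its pre-injection codons of the ancestor codon
    # index it derives from (None for inserted codons)
    codon_maps: dict[str, list[int | None]] = field(default_factory=dict)


def _random_ancestor(rng: np.random.Generator, n_codons: int) -> str:
    return "ATG" + "".join(
        _NONSTOP[rng.integers(len(_NONSTOP))] for _ in range(n_codons - 1)
    )


def inject_frameshift(
    seq: NucSeq, codon_pos: int, del_len: int
) -> tuple[NucSeq, tuple[str, int, int]]:
    """Delete ``del_len`` (1 or 2) nucleotides starting at the 1-based
    codon ``codon_pos``; returns the mutated sequence and the truth event
    ``("frameshift", codon_pos, del_len)``."""
    if del_len not in (1, 2):
        raise ParameterError("deletion length must be 1 or 2")
    n_codons = len(seq.residues) // 3
    if not 1 <= codon_pos <= n_codons:
        raise ParameterError(
            f"codon position {codon_pos} out of range 1..{n_codons}"
        )
    start = (codon_pos - 1) * 3
    residues = seq.residues[:start] + seq.residues[start + del_len :]
    return seq.with_residues(residues), ("frameshift", codon_pos, del_len)


def inject_stop(
    seq: NucSeq, codon_index: int, code: GeneticCode = STANDARD_CODE
) -> tuple[NucSeq, tuple[str, int, int]]:
    """Replace the 1-based internal codon ``codon_index`` with a stop
    triplet of the active code (terminal stops are free in the objective,
    hence useless as truth)."""
    n_codons = len(seq.residues) // 3
    if not 1 <= codon_index < n_codons:
        raise ParameterError(
            f"stop injection index {codon_index} must be internal (1..{n_codons - 1})"
        )
    stop = "TGA" if "TGA" in code.stop_codons else code.stop_codons[0]
    start = (codon_index - 1) * 3
    residues = seq.residues[:start] + stop + seq.residues[start + 3 :]
    return seq.with_residues(residues), ("internal_stop", codon_index, 0)


def evolve_orf(p: EvolutionParams) -> tuple[list[NucSeq], TruthRecord]:
    """Simulate one family; reproducible from ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    ancestor = _random_ancestor(rng, p.n_codons)
    truth = TruthRecord(ancestor=ancestor)
    seqs: list[NucSeq] = []
    for s in range(p.n_seqs):
        sid = f"seq{s}"
        codons = [ancestor[i : i + 3] for i in range(0, len(ancestor), 3)]
        cmap: list[int | None] = list(range(len(codons)))
        out_codons: list[str] = []
        out_map: list[int | None] = []
        for idx, codon in zip(cmap, codons):
            c = codon
            if rng.random() < p.sub_prob:
                c = _NONSTOP[rng.integers(len(_NONSTOP))]
            if p.indel_prob and rng.random() < p.indel_prob:
                if rng.random() < 0.5:
                    continue  # codon deletion
                out_codons.append(c)
                out_map.append(idx)
                out_codons.append(_NONSTOP[rng.integers(len(_NONSTOP))])
                out_map.append(None)  # codon insertion
                continue
            out_codons.append(c)
            out_map.append(idx)
        seq = NucSeq(sid, "".join(out_codons))
        truth.codon_maps[sid] = out_map
        truth.events[sid] = []
        seqs.append(seq)
    for s, codon_pos, del_len in p.frameshift_injections:
        sid = f"seq{s}"
        if not 0 <= s < p.n_seqs:
            raise ParameterError(f"sequence index {s} out of range")
        seq = next(q for q in seqs if q.id == sid)
        mutated, event = inject_frameshift(seq, codon_pos, del_len)
        seqs[seqs.index(seq)] = mutated
        truth.events[sid].append(event)
    for s, codon_index in p.stop_injections:
        sid = f"seq{s}"
        if not 0 <= s < p.n_seqs:
            raise ParameterError(f"sequence index {s} out of range")
        seq = next(q for q in seqs if q.id == sid)
        mutated, event = inject_stop(seq, codon_index)
        seqs[seqs.index(seq)] = mutated
        truth.events[sid].append(event)
    return seqs, truth


def frameshift_recovery_rate(
    n_replicates: int = 100,
    seed: int = 0,
    n_seqs: int = 5,
    n_codons: int = 100,
    sub_prob: float = 0.05,
    scheme=None,
    max_iter: int = 10,
    tolerance_codons: int = 1,
) -> float:
    """Fraction of replicates in which a single injected 1-nt deletion is
    recovered as a frameshift event in the right sequence within
    ``tolerance_codons`` of the injection.

    The injected sequence is placed in the low-penalty set and aligned with
    the guideline pseudogene penalties (fs -20, stop -10) unless another
    scheme is given; injections avoid the first and last three codons,
    where a frameshift degenerates into a terminal indel and is not an
    event at all.
    """
    from .pipeline import align_sequences
    from .scoring import ScoringScheme

    scheme = scheme or ScoringScheme(fs_lowpen=-20, stop_lowpen=-10)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        target = int(rng.integers(n_seqs))
        codon_pos = int(rng.integers(4, n_codons - 3))
        p = EvolutionParams(
            n_codons=n_codons,
            n_seqs=n_seqs,
            sub_prob=sub_prob,
            frameshift_injections=((target, codon_pos, 1),),
            seed=int(rng.integers(2**31 - 1)),
        )
        seqs, truth = evolve_orf(p)
        seqs = [
            replace(s, set_label="lowpen") if s.id == f"seq{target}" else s
            for s in seqs
        ]
        result = align_sequences(seqs, scheme, max_iter=max_iter)
        detected = [
            (e.nt_position - 1) // 3 + 1
            for e in result.alignment.events()
            if e.seq_id == f"seq{target}" and e.event_type == "frameshift"
        ]
        if any(abs(c - codon_pos) <= tolerance_codons for c in detected):
            hits += 1
    return hits / n_replicates
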