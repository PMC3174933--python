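"""End-to-end alignment pipeline: distances -> guide tree -> progressive
alignment -> 2-cut refinement."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import InputError
from .guide import GuideTree, build_guide_tree, kmer_distance_matrix
from .model import MultipleAlignment, NucSeq
from .msa import progressive_align, refine_2cut, retree_from_sp, sp_score
from .scoring import ScoringScheme

__all__ = ["AlignResult", "align_sequences"]


@dataclass
class AlignResult:
    alignment: MultipleAlignment
    tree: GuideTree | None
    sp_trajectory: list[int] = field(default_factory=list)

    @property
    def sp(self) -> int:
        return self.sp_trajectory[-1] if self.sp_trajectory else 0


def align_sequences(
    seqs: Sequence[NucSeq],
    scheme: ScoringScheme | None = None,
    k: int = 6,
    max_iter: int = 10,
    init_alignment: MultipleAlignment | None = None,
) -> AlignResult:
    """Align a set of coding sequences.

    With ``init_alignment`` the progressive stage is skipped and refinement
    starts from the provided alignment (its rows must match ``seqs``).
    """
    scheme = scheme or ScoringScheme()
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sequence ids")
    if len(seqs) == 1:
        A = MultipleAlignment.from_seq(seqs[0])
        return AlignResult(A, None, [0])
    if init_alignment is not None:
        if set(init_alignment.ids) != set(ids):
            raise InputError("initial alignment rows do not match input sequences")
        for s in seqs:
            if init_alignment.ungapped(s.id) != s.residues:
                raise InputError(
                    f"initial alignment row {s.id!r} does not ungap to the input"
                )
        A = init_alignment
        tree = retree_from_sp(A, scheme)
    else:
        tree = build_guide_tree(kmer_distance_matrix(seqs, k=k))
        A = progressive_align(seqs, tree, scheme)
    traj: list[int] = []
    A = refine_2cut(A, tree, scheme, max_iter=max_iter, trajectory=traj)
    A = A.reordered(ids)
    final_tree = retree_from_sp(A, scheme) if len(seqs) > 1 else None
    return AlignResult(A, final_tree, traj)
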