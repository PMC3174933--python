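"""Progressive multiple alignment and 2-cut refinement.

The multiple-alignment objective is the sum-of-pairs (SP) score: the sum
over all unordered row pairs of the induced pairwise alignment's score
under the same amino-acid-level, frameshift- and stop-aware objective as
the pairwise aligner (dual-gap columns dropped per pair, terminal events
and terminal gap runs free).

Merging is hierarchical along the guide tree:

* two leaves -> the full 15-move pairwise DP;
* a leaf against a block -> a hybrid 7-move DP consuming 0-1 block column
  and 0-3 nucleotides of the sequence, so the sequence can still be
  re-framed (new frameshifts) against the block;
* block against block -> a 3-move column DP.  Columns are atomic, so no
  new frameshifts can arise; the candidate merge maximises the cross-pair
  SP contribution with gap openings charged by Altschul's quasi-natural
  ("pessimistic") count.

Every merge preserves the induced sub-alignments of its operands exactly.
The initial progressive result is improved by 2-cut refinement: each guide
tree clade in turn is split out (dropping all-gap columns on each side),
re-merged, and the result kept only if the *natural* SP score strictly
improves; after each full sweep the guide tree is re-estimated from the
normalised SP contributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _dp
from .errors import InputError, ParameterError
from .guide import DistanceTable, GuideTree, TreeNode, build_guide_tree
from .model import (
    FRAMESHIFTED,
    FULL,
    GAP_SITE,
    MultipleAlignment,
    NucSeq,
    classify_site,
    pad_chunk,
)
from .pairwise import _codon_arrays, align_pair
from .scoring import RowInfo, ScoringScheme, score_induced_pair

__all__ = [
    "sp_score",
    "align_alignments",
    "align_sequence_to_alignment",
    "progressive_align",
    "refine_2cut",
    "retree_from_sp",
]


def sp_score(A: MultipleAlignment, scheme: ScoringScheme | None = None) -> int:
    """Sum-of-pairs score: Σ over row pairs of the induced pair's natural
    score."""
    scheme = scheme or ScoringScheme()
    total = 0
    for ia, ib in itertools.combinations(A.ids, 2):
        sa, sb = A.induced_pair(ia, ib)
        total += score_induced_pair(
            sa,
            sb,
            RowInfo(A.set_labels[ia], A.codes[ia]),
            RowInfo(A.set_labels[ib], A.codes[ib]),
            scheme,
        )
    return total


@dataclass
class _Profile:
    """Column-indexed scoring summaries of one block (1-based columns)."""

    nres: np.ndarray  # rows with content per column
    ngap: np.ndarray
    rr: np.ndarray  # rows with content in both c-1 and c
    gg: np.ndarray  # rows gapped in both c-1 and c
    events: np.ndarray  # summed fs/stop charges per column
    prof: np.ndarray  # (C+1, alphabet) counts of full non-stop sites
    n_rows: int


def _profile(A: MultipleAlignment, scheme: ScoringScheme) -> _Profile:
    C = A.ncols
    n = len(A.ids)
    nres = np.zeros(C + 1, np.int64)
    ngap = np.zeros(C + 1, np.int64)
    rr = np.zeros(C + 1, np.int64)
    gg = np.zeros(C + 1, np.int64)
    events = np.zeros(C + 1, np.int64)
    prof = np.zeros((C + 1, len(scheme.alphabet)), np.int64)
    for rid in A.ids:
        sites = A.rows[rid]
        info = RowInfo(A.set_labels[rid], A.codes[rid])
        content = [c for c, s in enumerate(sites) if s != GAP_SITE]
        last_c = content[-1] if content else -1
        total_nt = len(A.ungapped(rid))
        prev_res = False  # virtual pre-column counts as residue-less
        for c in range(C):
            site = sites[c]
            is_res = site != GAP_SITE
            if is_res:
                nres[c + 1] += 1
                kind = classify_site(site)
                if kind == FRAMESHIFTED:
                    forced_tail = (
                        c == last_c and (3 - site.count("!")) == total_nt % 3
                    )
                    if not forced_tail:
                        events[c + 1] += scheme.fs_for(info.set_label)
                else:
                    if info.code.is_stop(site):
                        if c != last_c:
                            events[c + 1] += scheme.stop_for(info.set_label)
                    else:
                        prof[c + 1, scheme.aa_index(info.code.translate_codon(site))] += 1
            else:
                ngap[c + 1] += 1
            if c >= 1:
                if is_res and prev_res:
                    rr[c + 1] += 1
                if not is_res and not prev_res:
                    gg[c + 1] += 1
            prev_res = is_res
    return _Profile(nres, ngap, rr, gg, events, prof, n)


def _merge_rows(
    A1: MultipleAlignment, A2: MultipleAlignment, ops: Sequence[tuple[int, int, int]]
) -> MultipleAlignment:
    """Assemble the merged alignment from column ops (state, p, q):
    state 0 pairs columns p/q, 1 takes p against gaps, 2 gaps against q."""
    rows: dict[str, list[str]] = {i: [] for i in (*A1.ids, *A2.ids)}
    for st, p, q in ops:
        for i in A1.ids:
            rows[i].append(A1.rows[i][p - 1] if st in (0, 1) else GAP_SITE)
        for i in A2.ids:
            rows[i].append(A2.rows[i][q - 1] if st in (0, 2) else GAP_SITE)
    return MultipleAlignment(
        [*A1.ids, *A2.ids],
        rows,
        {**A1.set_labels, **A2.set_labels},
        {**A1.codes, **A2.codes},
        validate=False,
    )


def _backtrack_ops(ps, P, Q, final_state, advance):
    """Shared backtracking over (state, p, q) tables; ``advance`` maps a
    state to its (dp, dq) consumption."""
    ops = []
    p, q, st = P, Q, final_state
    while (p, q) != (0, 0):
        prev = int(ps[st, p, q])
        dp, dq = advance(st, p, q)
        ops.append((st, p, q))
        p, q, st = p - dp, q - dq, prev
    ops.reverse()
    return ops


def align_alignments(
    A1: MultipleAlignment,
    A2: MultipleAlignment,
    scheme: ScoringScheme | None = None,
) -> MultipleAlignment:
    """Column-level merge of two alignments maximising the cross-pair SP
    objective; both induced sub-alignments are preserved exactly."""
    scheme = scheme or ScoringScheme()
    if set(A1.ids) & set(A2.ids):
        raise InputError("alignments share sequence ids")
    p1, p2 = _profile(A1, scheme), _profile(A2, scheme)
    P, Q = A1.ncols, A2.ncols
    # cross substitution+extension+event cost of pairing column p with q
    sub = (
        p2.n_rows * p1.events[:, None]
        + p1.n_rows * p2.events[None, :]
        + p1.prof @ scheme.matrix @ p2.prof.T
        + scheme.gap_ext * (p1.ngap[:, None] * p2.nres[None, :]
                            + p1.nres[:, None] * p2.ngap[None, :])
    ).astype(np.int64)
    S, D, I, ps = _dp.aln_aln_dp(
        P,
        Q,
        sub,
        p1.events,
        p2.events,
        p1.nres,
        p1.ngap,
        p1.rr,
        p1.gg,
        p2.nres,
        p2.ngap,
        p2.rr,
        p2.gg,
        np.int64(p1.n_rows),
        np.int64(p2.n_rows),
        np.int64(scheme.gap_open),
        np.int64(scheme.gap_ext),
    )
    finals = (S[P, Q], D[P, Q], I[P, Q])
    st = int(np.argmax(finals))
    ops = _backtrack_ops(
        ps, P, Q, st, lambda s, p, q: (1, 1) if s == 0 else ((1, 0) if s == 1 else (0, 1))
    )
    return _merge_rows(A1, A2, ops)


def align_sequence_to_alignment(
    s: NucSeq,
    A: MultipleAlignment,
    scheme: ScoringScheme | None = None,
) -> MultipleAlignment:
    """Hybrid 7-move merge of one sequence into a block: moves consume one
    block column against 0-3 nucleotides of ``s`` or insert an all-gap
    column against an ``s`` chunk, so new frameshifts can be placed in
    ``s``.  The induced alignment of ``A`` is preserved."""
    scheme = scheme or ScoringScheme()
    if s.id in A.ids:
        raise InputError(f"sequence {s.id!r} already in alignment")
    prof = _profile(A, scheme)
    P, m = A.ncols, len(s.residues)
    aaS, stopS = _codon_arrays(s.residues, s.code, scheme)
    matprof = (prof.prof @ scheme.matrix).astype(np.int64)
    S, D, I, ps, pm = _dp.seq_aln_dp(
        np.int64(P),
        np.int64(m),
        prof.events,
        prof.nres,
        prof.ngap,
        prof.rr,
        prof.gg,
        matprof,
        np.int64(prof.n_rows),
        aaS,
        stopS,
        np.int64(scheme.gap_open),
        np.int64(scheme.gap_ext),
        np.int64(scheme.fs_for(s.set_label)),
        np.int64(scheme.stop_for(s.set_label)),
    )
    finals = (S[P, m], D[P, m], I[P, m])
    st = int(np.argmax(finals))
    ops = _backtrack_ops(
        ps,
        P,
        m,
        st,
        lambda state, p, j: (
            (1, int(pm[state, p, j]))
            if state == 0
            else ((1, 0) if state == 1 else (0, int(pm[state, p, j])))
        ),
    )
    rows: dict[str, list[str]] = {i: [] for i in A.ids}
    srow: list[str] = []
    j = 0
    for state, p, jj in ops:
        db = int(pm[state, p, jj]) if state in (0, 2) else 0
        for i in A.ids:
            rows[i].append(A.rows[i][p - 1] if state in (0, 1) else GAP_SITE)
        srow.append(GAP_SITE if db == 0 else pad_chunk(s.residues[j : j + db]))
        j += db
    rows[s.id] = srow
    return MultipleAlignment(
        [*A.ids, s.id],
        rows,
        {**A.set_labels, s.id: s.set_label},
        {**A.codes, s.id: s.code},
        validate=False,
    )


def _merge(
    left: MultipleAlignment, right: MultipleAlignment, scheme: ScoringScheme
) -> MultipleAlignment:
    """Dispatch a merge on operand shapes (leaf-aware)."""
    if len(left.ids) == 1 and len(right.ids) == 1:
        a = left.to_nucseq(left.ids[0])
        b = right.to_nucseq(right.ids[0])
        pa = align_pair(a, b, scheme)
        return pa.to_msa(
            {a.id: a.set_label, b.id: b.set_label},
            {a.id: a.code, b.id: b.code},
        )
    if len(right.ids) == 1:
        return align_sequence_to_alignment(right.to_nucseq(right.ids[0]), left, scheme)
    if len(left.ids) == 1:
        return align_sequence_to_alignment(left.to_nucseq(left.ids[0]), right, scheme)
    return align_alignments(left, right, scheme)


def progressive_align(
    seqs: Sequence[NucSeq],
    tree: GuideTree,
    scheme: ScoringScheme | None = None,
) -> MultipleAlignment:
    """Post-order merge of the guide tree's clades."""
    scheme = scheme or ScoringScheme()
    by_id = {s.id: s for s in seqs}
    if set(by_id) != set(tree.leaf_ids()):
        raise InputError("guide tree leaves do not match sequence ids")

    def rec(node: TreeNode) -> MultipleAlignment:
        if node.is_leaf:
            return MultipleAlignment.from_seq(by_id[node.name])
        return _merge(rec(node.children[0]), rec(node.children[1]), scheme)

    return rec(tree.root)


def retree_from_sp(
    A: MultipleAlignment, scheme: ScoringScheme | None = None
) -> GuideTree:
    """Guide tree re-estimated from normalised SP contributions: pair
    similarity = induced score / max(self score), distance = 1 - sim
    clamped to [0, 1]."""
    scheme = scheme or ScoringScheme()
    if len(A.ids) < 2:
        raise InputError("need at least 2 rows")
    ids = tuple(A.ids)
    selfscore = {}
    for i in ids:
        sites = [s for s in A.rows[i] if s != GAP_SITE]
        info = RowInfo(A.set_labels[i], A.codes[i])
        selfscore[i] = score_induced_pair(sites, sites, info, info, scheme)
    n = len(ids)
    d = np.zeros((n, n))
    for x, y in itertools.combinations(range(n), 2):
        ia, ib = ids[x], ids[y]
        sa, sb = A.induced_pair(ia, ib)
        sc = score_induced_pair(
            sa,
            sb,
            RowInfo(A.set_labels[ia], A.codes[ia]),
            RowInfo(A.set_labels[ib], A.codes[ib]),
            scheme,
        )
        denom = max(selfscore[ia], selfscore[ib])
        sim = sc / denom if denom > 0 else 0.0
        d[x, y] = d[y, x] = min(1.0, max(0.0, 1.0 - sim))
    return build_guide_tree(DistanceTable(ids, d))


def refine_2cut(
    A: MultipleAlignment,
    tree: GuideTree,
    scheme: ScoringScheme | None = None,
    max_iter: int = 10,
    trajectory: list | None = None,
) -> MultipleAlignment:
    """Iterative 2-cut refinement: split along each guide-tree clade,
    re-merge, keep only strict SP improvements; re-estimate the tree after
    each full sweep.  The final score is >= the initial one."""
    scheme = scheme or ScoringScheme()
    if max_iter < 0:
        raise ParameterError("max_iter must be >= 0")
    cur = A
    cur_sp = sp_score(cur, scheme)
    if trajectory is not None:
        trajectory.append(cur_sp)
    all_ids = set(A.ids)
    for _ in range(max_iter):
        improved = False
        for clade in tree.clades():
            inside = set(clade.leaf_ids())
            outside = all_ids - inside
            if not outside:
                continue
            sub_in = cur.subset(inside)
            sub_out = cur.subset(outside)
            cand = _merge(sub_out, sub_in, scheme)
            cand_sp = sp_score(cand, scheme)
            if cand_sp > cur_sp:
                cur, cur_sp = cand.reordered(A.ids), cand_sp
                improved = True
                if trajectory is not None:
                    trajectory.append(cur_sp)
        if not improved:
            break
        tree = retree_from_sp(cur, scheme)
    return cur
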