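"""Numba kernels for the three dynamic programmes.

All kernels maximise an integer score with a large negative sentinel for
unreachable cells; only the (0,0) cell of the match state is initialised,
every other boundary cell is reached through the sentinel-guarded
recursion.  Ties are broken by fixed candidate order (fewer frameshifts
first, then lexicographically larger move, then previous state
match > deletion > insertion), which makes backtracking deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(1 << 40))

# match-state moves (da, db) in tie-break priority order
M_DA = np.array([3, 3, 3, 2, 1, 2, 2, 1, 1], dtype=np.int64)
M_DB = np.array([3, 2, 1, 3, 3, 2, 1, 2, 1], dtype=np.int64)


@njit(cache=True)
def _ev_a(da, i, n, stop, st_pen, fs_pen, ge):
    """Event score of the chunk ending at prefix length i of a length-n row.

    The forced incomplete tail codon (trailing chunk of length n mod 3) is
    free; terminal stops are free; every other frameshifted chunk pays the
    frameshift score.  ``ge`` is unused but kept in the signature shared by
    all kernels."""
    if da == 3:
        if stop[i] and i < n:
            return st_pen
        return 0
    if i == n and da == n % 3:
        return 0
    return fs_pen


@njit(cache=True)
def pair_dp(n, m, aaA, stopA, aaB, stopB, mat, go, ge, fsA, fsB, stA, stB):
    """15-move, three-state affine DP over two nucleotide sequences.

    Returns the three score tables plus per-state backpointers
    (previous state and encoded move ``da*4+db``).
    """
    M = np.full((n + 1, m + 1), NEG, np.int64)
    D = np.full((n + 1, m + 1), NEG, np.int64)
    I = np.full((n + 1, m + 1), NEG, np.int64)
    ps = np.full((3, n + 1, m + 1), -1, np.int8)
    pm = np.zeros((3, n + 1, m + 1), np.int8)
    M[0, 0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            # --- match/substitution state: 9 moves with da>=1, db>=1
            best = NEG
            bps = np.int8(-1)
            bmv = np.int8(0)
            for k in range(9):
                da = M_DA[k]
                db = M_DB[k]
                pi = i - da
                pj = j - db
                if pi < 0 or pj < 0:
                    continue
                s = _ev_a(da, i, n, stopA, stA, fsA, ge) + _ev_a(db, j, m, stopB, stB, fsB, ge)
                if da == 3 and db == 3 and not stopA[i] and not stopB[j]:
                    s += mat[aaA[i], aaB[j]]
                for p in range(3):
                    if p == 0:
                        pv = M[pi, pj]
                    elif p == 1:
                        pv = D[pi, pj]
                    else:
                        pv = I[pi, pj]
                    cand = pv + s
                    if cand > best:
                        best = cand
                        bps = np.int8(p)
                        bmv = np.int8(da * 4 + db)
            M[i, j] = best
            ps[0, i, j] = bps
            pm[0, i, j] = bmv
            # --- deletion state: consume a, gap site in b; free at b ends
            free = j == 0 or j == m
            best = NEG
            bps = np.int8(-1)
            bmv = np.int8(0)
            for da in (3, 2, 1):
                pi = i - da
                if pi < 0:
                    continue
                s = _ev_a(da, i, n, stopA, stA, fsA, ge)
                if not free:
                    s += ge
                for p in range(3):
                    if p == 0:
                        pv = M[pi, j]
                    elif p == 1:
                        pv = D[pi, j]
                    else:
                        pv = I[pi, j]
                    cand = pv + s
                    if p != 1 and not free:
                        cand += go
                    if cand > best:
                        best = cand
                        bps = np.int8(p)
                        bmv = np.int8(da * 4)
            D[i, j] = best
            ps[1, i, j] = bps
            pm[1, i, j] = bmv
            # --- insertion state: consume b, gap site in a; free at a ends
            free = i == 0 or i == n
            best = NEG
            bps = np.int8(-1)
            bmv = np.int8(0)
            for db in (3, 2, 1):
                pj = j - db
                if pj < 0:
                    continue
                s = _ev_a(db, j, m, stopB, stB, fsB, ge)
                if not free:
                    s += ge
                for p in range(3):
                    if p == 0:
                        pv = M[i, pj]
                    elif p == 1:
                        pv = D[i, pj]
                    else:
                        pv = I[i, pj]
                    cand = pv + s
                    if p != 2 and not free:
                        cand += go
                    if cand > best:
                        best = cand
                        bps = np.int8(p)
                        bmv = np.int8(db)
            I[i, j] = best
            ps[2, i, j] = bps
            pm[2, i, j] = bmv
    return M, D, I, ps, pm


@njit(cache=True)
def seq_aln_dp(
    P,
    m,
    es1,
    nres1,
    ngap1,
    rr1,
    gg1,
    matprof,
    n1,
    aaS,
    stopS,
    go,
    ge,
    fs_s,
    st_s,
):
    """Hybrid 7-move DP aligning one sequence against an alignment.

    Side 1 is the block (columns are atomic, described by the count
    vectors and the profile-vs-aa score table ``matprof``); side 2 is the
    sequence, which may be re-framed (new frameshifts).  Gap openings are
    charged with Altschul's quasi-natural count against the block's
    per-column gap configuration.
    """
    S = np.full((P + 1, m + 1), NEG, np.int64)
    D = np.full((P + 1, m + 1), NEG, np.int64)
    I = np.full((P + 1, m + 1), NEG, np.int64)
    ps = np.full((3, P + 1, m + 1), -1, np.int8)
    pm = np.zeros((3, P + 1, m + 1), np.int8)
    S[0, 0] = 0
    for p in range(P + 1):
        for j in range(m + 1):
            if p == 0 and j == 0:
                continue
            # --- S: block column p faces a 1-3 nt chunk of s
            best = NEG
            bps = np.int8(-1)
            bmv = np.int8(0)
            if p >= 1:
                for db in (3, 2, 1):
                    pj = j - db
                    if pj < 0:
                        continue
                    ev = _ev_a(db, j, m, stopS, st_s, fs_s, ge)
                    s = es1[p] + n1 * ev + ge * ngap1[p]
                    if db == 3 and not stopS[j]:
                        s += matprof[p, aaS[j]]
                    for q in range(3):
                        if q == 0:
                            pv = S[p - 1, pj]
                            opn = ngap1[p] - gg1[p]
                        elif q == 1:
                            pv = D[p - 1, pj]
                            opn = ngap1[p]
                        else:
                            pv = I[p - 1, pj]
                            opn = 0
                        if p - 1 == 0 and pj == 0:
                            opn = 0
                        cand = pv + s + go * opn
                        if cand > best:
                            best = cand
                            bps = np.int8(q)
                            bmv = np.int8(db)
            S[p, j] = best
            ps[0, p, j] = bps
            pm[0, p, j] = bmv
            # --- D: block column p faces a gap in s; free at s ends
            best = NEG
            bps = np.int8(-1)
            bmv = np.int8(0)
            if p >= 1:
                free = j == 0 or j == m
                s = es1[p]
                if not free:
                    s += ge * nres1[p]
                for q in range(3):
                    if q == 0:
                        pv = S[p - 1, j]
                        opn = nres1[p]
                    elif q == 1:
                        pv = D[p - 1, j]
                        opn = nres1[p] - rr1[p]
                    else:
                        pv = I[p - 1, j]
                        opn = nres1[p]
                    if free or (p - 1 == 0 and j == 0):
                        opn = 0
                    cand = pv + s + go * opn
                    if cand > best:
                        best = cand
                        bps = np.int8(q)
                        bmv = np.int8(0)
            D[p, j] = best
            ps[1, p, j] = bps
            pm[1, p, j] = bmv
            # --- I: all-gap column inserted in the block faces an s chunk
            best = NEG
            bps = np.int8(-1)
            bmv = np.int8(0)
            free = p == 0 or p == P
            for db in (3, 2, 1):
                pj = j - db
                if pj < 0:
                    continue
                ev = _ev_a(db, j, m, stopS, st_s, fs_s, ge)
                s = n1 * ev
                if not free:
                    s += ge * n1
                for q in range(3):
                    if q == 0:
                        pv = S[p, pj]
                        opn = nres1[p]
                    elif q == 1:
                        pv = D[p, pj]
                        opn = n1
                    else:
                        pv = I[p, pj]
                        opn = 0
                    if free or (p == 0 and pj == 0):
                        opn = 0
                    cand = pv + s + go * opn
                    if cand > best:
                        best = cand
                        bps = np.int8(q)
                        bmv = np.int8(db)
            I[p, j] = best
            ps[2, p, j] = bps
            pm[2, p, j] = bmv
    return S, D, I, ps, pm



@njit(cache=True)
def aln_aln_dp(
    P,
    Q,
    sub,
    es1,
    es2,
    nres1,
    ngap1,
    rr1,
    gg1,
    nres2,
    ngap2,
    rr2,
    gg2,
    n1,
    n2,
    go,
    ge,
):
    """Column-level 3-move DP aligning two alignments under cross-pair SP
    with quasi-natural gap-opening counts.  Columns are atomic: no new
    frameshifts can arise here."""
    S = np.full((P + 1, Q + 1), NEG, np.int64)
    D = np.full((P + 1, Q + 1), NEG, np.int64)
    I = np.full((P + 1, Q + 1), NEG, np.int64)
    ps = np.full((3, P + 1, Q + 1), -1, np.int8)
    S[0, 0] = 0
    for p in range(P + 1):
        for q in range(Q + 1):
            if p == 0 and q == 0:
                continue
            # --- S: column p of block 1 faces column q of block 2
            best = NEG
            bps = np.int8(-1)
            if p >= 1 and q >= 1:
                s = sub[p, q]
                for st in range(3):
                    if st == 0:
                        pv = S[p - 1, q - 1]
                        opn = (
                            nres1[p] * ngap2[q]
                            - rr1[p] * gg2[q]
                            + ngap1[p] * nres2[q]
                            - gg1[p] * rr2[q]
                        )
                    elif st == 1:
                        pv = D[p - 1, q - 1]
                        opn = (nres1[p] - rr1[p]) * ngap2[q] + ngap1[p] * nres2[q]
                    else:
                        pv = I[p - 1, q - 1]
                        opn = nres1[p] * ngap2[q] + ngap1[p] * (nres2[q] - rr2[q])
                    if p - 1 == 0 and q - 1 == 0:
                        opn = 0
                    cand = pv + s + go * opn
                    if cand > best:
                        best = cand
                        bps = np.int8(st)
            S[p, q] = best
            ps[0, p, q] = bps
            # --- D: column p of block 1 faces all-gap in block 2
            best = NEG
            bps = np.int8(-1)
            if p >= 1:
                free = q == 0 or q == Q
                s = n2 * es1[p]
                if not free:
                    s += ge * nres1[p] * n2
                for st in range(3):
                    if st == 0:
                        pv = S[p - 1, q]
                        opn = nres1[p] * n2 - rr1[p] * ngap2[q]
                    elif st == 1:
                        pv = D[p - 1, q]
                        opn = (nres1[p] - rr1[p]) * n2
                    else:
                        pv = I[p - 1, q]
                        opn = nres1[p] * n2
                    if free or (p - 1 == 0 and q == 0):
                        opn = 0
                    cand = pv + s + go * opn
                    if cand > best:
                        best = cand
                        bps = np.int8(st)
            D[p, q] = best
            ps[1, p, q] = bps
            # --- I: all-gap in block 1 faces column q of block 2
            best = NEG
            bps = np.int8(-1)
            if q >= 1:
                free = p == 0 or p == P
                s = n1 * es2[q]
                if not free:
                    s += ge * nres2[q] * n1
                for st in range(3):
                    if st == 0:
                        pv = S[p, q - 1]
                        opn = nres2[q] * n1 - rr2[q] * ngap1[p]
                    elif st == 1:
                        pv = D[p, q - 1]
                        opn = nres2[q] * n1
                    else:
                        pv = I[p, q - 1]
                        opn = (nres2[q] - rr2[q]) * n1
                    if free or (p == 0 and q - 1 == 0):
                        opn = 0
                    cand = pv + s + go * opn
                    if cand > best:
                        best = cand
                        bps = np.int8(st)
            I[p, q] = best
            ps[2, p, q] = bps
    return S, D, I, ps
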