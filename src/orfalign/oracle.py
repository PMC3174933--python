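"""Independent reference aligners used to validate the production DP.

Two levels of trust:

* :func:`enumerate_alignments` / :func:`brute_best` - literally enumerate
  every sequence of moves consuming both inputs and score each finished
  column list with the natural scorer
  (:func:`orfalign.scoring.score_induced_pair`).  Exponential; only for a
  handful of nucleotides.
* :func:`oracle_align` - a plain memoised recursion over (consumed-a,
  consumed-b, previous-column state).  It shares no code with the
  production table-filling kernel (no sentinels, no matrices) and is itself
  checked against the exhaustive enumerator on tiny inputs.

Both accept the full 15-move set by default; a restricted move set (e.g.
codon-unit moves only on one side) can be passed for cross-checks.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .codes import GeneticCode, STANDARD_CODE
from .errors import OracleSizeError
from .model import GAP_SITE, NucSeq, pad_chunk
from .scoring import RowInfo, ScoringScheme, score_induced_pair

__all__ = ["ALL_MOVES", "oracle_align", "enumerate_alignments", "brute_best"]

#: the 15 admissible (da, db) moves: 0-3 nucleotides from each side, not (0,0)
ALL_MOVES: tuple[tuple[int, int], ...] = tuple(
    (da, db) for da in range(4) for db in range(4) if (da, db) != (0, 0)
)

_NEG = float("-inf")


def _as_parts(seq) -> tuple[str, str, GeneticCode]:
    if isinstance(seq, NucSeq):
        return seq.residues, seq.set_label, seq.code
    return str(seq), "reliable", STANDARD_CODE


def _move_priority(da: int, db: int) -> tuple:
    fs = (1 if da in (1, 2) else 0) + (1 if db in (1, 2) else 0)
    return (fs, -da, -db)


def oracle_align(
    a,
    b,
    scheme: ScoringScheme | None = None,
    moves: Iterable[tuple[int, int]] = ALL_MOVES,
    max_total: int = 24,
):
    """Maximum-score alignment by memoised recursion; returns
    ``(score, (sites_a, sites_b))``.

    Refuses inputs with more than ``max_total`` combined nucleotides (the
    enumeration behind this oracle family is exponential and it is only
    meant for validation at toy sizes).
    """
    scheme = scheme or ScoringScheme()
    ra, set_a, code_a = _as_parts(a)
    rb, set_b, code_b = _as_parts(b)
    na, nb = len(ra), len(rb)
    if na + nb > max_total:
        raise OracleSizeError(
            f"oracle refuses {na}+{nb} nt (limit {max_total}); use align_pair"
        )
    fs_a, st_a = scheme.fs_for(set_a), scheme.stop_for(set_a)
    fs_b, st_b = scheme.fs_for(set_b), scheme.stop_for(set_b)
    go, ge = scheme.gap_open, scheme.gap_ext
    move_list = sorted(moves, key=lambda m: _move_priority(*m))

    def col_score(i: int, da: int, j: int, db: int, prev: str) -> int:
        s = 0
        if da in (1, 2):
            # only the forced incomplete tail codon is a free non-event
            if not (i + da == na and da == na % 3):
                s += fs_a
        elif da == 3:
            if code_a.is_stop(ra[i : i + 3]) and i + 3 < na:
                s += st_a
        if db in (1, 2):
            if not (j + db == nb and db == nb % 3):
                s += fs_b
        elif db == 3:
            if code_b.is_stop(rb[j : j + 3]) and j + 3 < nb:
                s += st_b
        if da == 3 and db == 3:
            ca, cb = ra[i : i + 3], rb[j : j + 3]
            if not code_a.is_stop(ca) and not code_b.is_stop(cb):
                s += scheme.sub(code_a.translate_codon(ca), code_b.translate_codon(cb))
        if da == 0:  # gap site in row a; free at row-a extremities
            if not (i == 0 or i == na):
                s += ge + (go if prev != "I" else 0)
        if db == 0:
            if not (j == 0 or j == nb):
                s += ge + (go if prev != "D" else 0)
        return s

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == na and j == nb:
            return 0
        out = _NEG
        for da, db in move_list:
            if i + da > na or j + db > nb:
                continue
            state = "S" if (da and db) else ("D" if da else "I")
            r = col_score(i, da, j, db, prev) + best(i + da, j + db, state)
            if r > out:
                out = r
        return out

    score = best(0, 0, "^")
    # deterministic reconstruction following the memoised values
    i = j = 0
    prev = "^"
    sites_a: list[str] = []
    sites_b: list[str] = []
    while (i, j) != (na, nb):
        for da, db in move_list:
            if i + da > na or j + db > nb:
                continue
            state = "S" if (da and db) else ("D" if da else "I")
            if (
                col_score(i, da, j, db, prev) + best(i + da, j + db, state)
                == best(i, j, prev)
            ):
                sites_a.append(GAP_SITE if da == 0 else pad_chunk(ra[i : i + da]))
                sites_b.append(GAP_SITE if db == 0 else pad_chunk(rb[j : j + db]))
                i, j, prev = i + da, j + db, state
                break
        else:  # pragma: no cover
            raise RuntimeError("oracle backtrack failed")
    return int(score), (tuple(sites_a), tuple(sites_b))


def enumerate_alignments(
    ra: str,
    rb: str,
    moves: Iterable[tuple[int, int]] = ALL_MOVES,
    max_total: int = 12,
):
    """Yield every alignment (list of site pairs) of two raw strings."""
    if len(ra) + len(rb) > max_total:
        raise OracleSizeError(f"exhaustive enumeration refuses {len(ra)}+{len(rb)} nt")
    move_list = list(moves)

    def rec(i: int, j: int, acc: list):
        if i == len(ra) and j == len(rb):
            yield list(acc)
            return
        for da, db in move_list:
            if i + da > len(ra) or j + db > len(rb):
                continue
            acc.append(
                (
                    GAP_SITE if da == 0 else pad_chunk(ra[i : i + da]),
                    GAP_SITE if db == 0 else pad_chunk(rb[j : j + db]),
                )
            )
            yield from rec(i + da, j + db, acc)
            acc.pop()

    yield from rec(0, 0, [])


def brute_best(a, b, scheme: ScoringScheme | None = None, max_total: int = 12) -> int:
    """Exhaustive maximum over all alignments, scored by the natural scorer."""
    scheme = scheme or ScoringScheme()
    ra, set_a, code_a = _as_parts(a)
    rb, set_b, code_b = _as_parts(b)
    info_a, info_b = RowInfo(set_a, code_a), RowInfo(set_b, code_b)
    best = None
    for cols in enumerate_alignments(ra, rb, max_total=max_total):
        s = score_induced_pair(
            [c[0] for c in cols], [c[1] for c in cols], info_a, info_b, scheme
        )
        if best is None or s > best:
            best = s
    return best
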