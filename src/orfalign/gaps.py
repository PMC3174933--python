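"""Gap-opening counts for sum-of-pairs alignment of alignments.

When two alignments are merged column-wise, the gap-extension part of the
SP score is a simple per-column count, but the number of gap *openings*
each merge decision implies for every cross pair of rows is what makes
aligning alignments hard.  Counting openings exactly (dropping dual-gap
columns per pair first) cannot be folded into a low-state dynamic
programme, so the merge DP uses Altschul's quasi-natural ("pessimistic")
count: scan the unreduced pair projection column by column and count every
start of a gap-vs-residue run, where a dual-gap column breaks runs.  The
quasi-natural count equals the natural one except when a gap run is
interrupted by dual-gap columns and resumes on the same side, where it
counts one opening too many - hence "pessimistic".

The two counters here operate on explicit per-row gap patterns and serve
as the reference the DP kernels' factorised opening formulas are tested
against.
"""

from __future__ import annotations

__all__ = ["natural_gap_openings", "quasi_natural_gap_openings"]


def _check(pattern: str) -> str:
    if set(pattern) - {"R", "-"}:
        raise ValueError(f"pattern must be over 'R'/'-', got {pattern!r}")
    return pattern


def natural_gap_openings(ga: str, gb: str) -> int:
    """Exact opening count of one row pair: drop dual-gap columns, then
    count maximal gap runs in either row.  Patterns use ``R`` for residue
    and ``-`` for gap."""
    _check(ga), _check(gb)
    if len(ga) != len(gb):
        raise ValueError("patterns differ in length")
    cols = [(a, b) for a, b in zip(ga, gb) if (a, b) != ("-", "-")]
    n = 0
    for row in (0, 1):
        prev = "R"
        for col in cols:
            if col[row] == "-" and prev == "R":
                n += 1
            prev = col[row]
    return n


def quasi_natural_gap_openings(ga: str, gb: str) -> int:
    """Altschul's pessimistic opening count: count starts of
    gap-vs-residue runs in the *unreduced* projection; dual-gap columns
    interrupt runs (and may cause over-counting, never under-counting)."""
    _check(ga), _check(gb)
    if len(ga) != len(gb):
        raise ValueError("patterns differ in length")
    n = 0
    prev = ("R", "R")
    for col in zip(ga, gb):
        for row in (0, 1):
            other = 1 - row
            if col[row] == "-" and col[other] == "R":
                if not (prev[row] == "-" and prev[other] == "R"):
                    n += 1
        prev = col
    return n
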