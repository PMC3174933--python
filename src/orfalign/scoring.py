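"""Amino-acid-level scoring of codon-site alignments.

The alignment objective is additive and maximised.  Every column contributes
the sum of:

* a frameshift score (default -30) for each side whose site is
  frameshifted, unless that site sits at the row's extremity (a trailing or
  leading partial codon is an ordinary terminal indel and costs nothing);
* a stop score (default -100) for each side that is an *internal* stop
  codon - a stop occupying the row's final codon position is free;
* the substitution-matrix entry of the two translations when both sides are
  full, non-stop codons (BLOSUM62 by default; codons containing ``N``
  translate to ``X``);
* one gap-extension score (default -1) for a gap side, with the gap-opening
  surcharge (default -7) accounted for per maximal gap run by the dynamic
  programme / scorer, and terminal gap runs free (semi-global convention).

No substitution term is added when either side is frameshifted or a stop;
those events are penalised on their own, so ``*`` facing ``!`` costs
stop + fs.  Sequences flagged ``lowpen`` (pseudogenes, raw reads) use the
softer ``fs_lowpen`` / ``stop_lowpen`` scores for their own events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .codes import GeneticCode, STANDARD_CODE
from .errors import ConfigError, InvalidColumnError
from .model import FRAMESHIFTED, FULL, GAP, GAP_SITE, classify_site

__all__ = ["ScoringScheme", "site_score", "score_induced_pair", "RowInfo"]


@lru_cache(maxsize=None)
def _blosum62() -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    arr = np.asarray(mat, dtype=np.int64)
    return alphabet, arr


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap, frameshift and stop scores.

    All penalties are integers <= 0.  ``fs_lowpen`` / ``stop_lowpen`` default
    to the main values and apply to rows labelled ``lowpen``.
    """

    gap_open: int = -7
    gap_ext: int = -1
    fs: int = -30
    stop: int = -100
    fs_lowpen: int | None = None
    stop_lowpen: int | None = None
    matrix_name: str = "BLOSUM62"
    alphabet: str = field(init=False, repr=False)
    matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("gap_open", "gap_ext", "fs", "stop"):
            if getattr(self, name) > 0:
                raise ConfigError(f"{name} must be <= 0")
        if self.fs_lowpen is None:
            object.__setattr__(self, "fs_lowpen", self.fs)
        if self.stop_lowpen is None:
            object.__setattr__(self, "stop_lowpen", self.stop)
        if self.fs_lowpen > 0 or self.stop_lowpen > 0:
            raise ConfigError("per-set penalties must be <= 0")
        if self.matrix_name != "BLOSUM62":
            mat = substitution_matrices.load(self.matrix_name)
            alphabet, arr = str(mat.alphabet), np.asarray(mat, dtype=np.int64)
        else:
            alphabet, arr = _blosum62()
        if not np.array_equal(arr, arr.T):
            raise ConfigError("substitution matrix must be symmetric")
        object.__setattr__(self, "alphabet", alphabet)
        object.__setattr__(self, "matrix", arr)

    def aa_index(self, aa: str) -> int:
        i = self.alphabet.find(aa)
        if i < 0:
            raise ConfigError(f"symbol {aa!r} not in matrix alphabet")
        return i

    def sub(self, aa_a: str, aa_b: str) -> int:
        return int(self.matrix[self.aa_index(aa_a), self.aa_index(aa_b)])

    def fs_for(self, set_label: str) -> int:
        return int(self.fs_lowpen if set_label == "lowpen" else self.fs)

    def stop_for(self, set_label: str) -> int:
        return int(self.stop_lowpen if set_label == "lowpen" else self.stop)


@dataclass(frozen=True)
class RowInfo:
    """Per-row scoring metadata: penalty set and genetic code."""

    set_label: str = "reliable"
    code: GeneticCode = STANDARD_CODE


def _event_score(
    site: str,
    kind: str,
    info: RowInfo,
    scheme: ScoringScheme,
    forced_tail: bool,
    last: bool,
) -> int:
    """Frameshift/stop contribution of one content site of one row.

    ``forced_tail`` marks the trailing incomplete codon a sequence whose
    length is not a multiple of 3 necessarily ends with: that partial codon
    is an accident of sequence extent, not a frameshift event, and is free.
    Every other frameshifted site - re-framing chunks at either end
    included - pays the frameshift score.  A stop codon is free only in the
    row's last codon position (``last``).
    """
    if kind == FRAMESHIFTED:
        return 0 if forced_tail else scheme.fs_for(info.set_label)
    if kind == FULL and info.code.is_stop(site):
        return 0 if last else scheme.stop_for(info.set_label)
    return 0


def site_score(
    a: str,
    b: str,
    row_set_a: str = "reliable",
    row_set_b: str = "reliable",
    scheme: ScoringScheme | None = None,
    code: GeneticCode = STANDARD_CODE,
    code_b: GeneticCode | None = None,
    a_terminal: bool = False,
    b_terminal: bool = False,
) -> int:
    """Score one aligned column of two codon sites.

    Gap-opening bookkeeping is *not* included: a gap side contributes one
    ``gap_ext``; run-level opening surcharges and terminal-run exemptions
    are the caller's concern (see :func:`score_induced_pair`).  The
    ``*_terminal`` flags mark a site occupying its row's final codon
    position (a forced incomplete tail codon or a terminal stop), which
    lifts the event penalty for that side.
    """
    scheme = scheme or ScoringScheme()
    code_b = code_b or code
    ka, kb = classify_site(a), classify_site(b)
    if ka == GAP and kb == GAP:
        raise InvalidColumnError("column is gap in both rows")
    total = 0
    info_a = RowInfo(row_set_a, code)
    info_b = RowInfo(row_set_b, code_b)
    total += _event_score(a, ka, info_a, scheme, a_terminal, a_terminal)
    total += _event_score(b, kb, info_b, scheme, b_terminal, b_terminal)
    if ka == GAP or kb == GAP:
        return total + scheme.gap_ext
    if (
        ka == FULL
        and kb == FULL
        and not info_a.code.is_stop(a)
        and not info_b.code.is_stop(b)
    ):
        total += scheme.sub(
            info_a.code.translate_codon(a), info_b.code.translate_codon(b)
        )
    return total


def score_induced_pair(
    sites_a: Sequence[str],
    sites_b: Sequence[str],
    info_a: RowInfo,
    info_b: RowInfo,
    scheme: ScoringScheme,
) -> int:
    """Natural (run-level) score of a finished two-row alignment.

    This is the reference objective: dual-gap columns are dropped, each
    maximal internal gap run costs ``gap_open + len * gap_ext``, terminal
    gap runs are free, and event/substitution terms follow
    :func:`site_score`.  Both the pairwise DP and the sum-of-pairs criterion
    are defined against this function.
    """
    cols = [
        (a, b)
        for a, b in zip(sites_a, sites_b)
        if not (a == GAP_SITE and b == GAP_SITE)
    ]
    if not cols:
        return 0
    n = len(cols)
    total = 0
    for row, info in ((0, info_a), (1, info_b)):
        content = [c for c in range(n) if cols[c][row] != GAP_SITE]
        last_c = content[-1] if content else -1
        total_nt = sum(3 - cols[c][row].count("!") for c in content)
        for c in content:
            site = cols[c][row]
            kind = classify_site(site)
            forced_tail = (
                kind == FRAMESHIFTED
                and c == last_c
                and (3 - site.count("!")) == total_nt % 3
            )
            total += _event_score(site, kind, info, scheme, forced_tail, c == last_c)
        # maximal gap runs of this row; terminal runs are free
        c = 0
        while c < n:
            if cols[c][row] == GAP_SITE:
                start = c
                while c < n and cols[c][row] == GAP_SITE:
                    c += 1
                if start != 0 and c != n:
                    total += scheme.gap_open + (c - start) * scheme.gap_ext
            else:
                c += 1
    for a, b in cols:
        if a == GAP_SITE or b == GAP_SITE:
            continue
        if (
            classify_site(a) == FULL
            and classify_site(b) == FULL
            and not info_a.code.is_stop(a)
            and not info_b.code.is_stop(b)
        ):
            total += scheme.sub(
                info_a.code.translate_codon(a), info_b.code.translate_codon(b)
            )
    return total
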