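"""Core data containers: sequences, codon sites, alignments, events.

A *codon site* is the atom of every alignment produced here: a 3-character
cell over ``{A,C,G,T,N,!,-}``.  Exactly one of three kinds:

* ``GAP`` - the cell is ``---``;
* ``FRAMESHIFTED`` - 1 or 2 ``!`` padding a partial codon (a 1-2 nt
  deletion disrupting the reading frame);
* ``FULL`` - three nucleotide symbols (possibly containing ``N``).

Mixed ``-``/nucleotide or ``-``/``!`` triplets are invalid.  Deleting every
``-`` and ``!`` from a row of sites reconstructs the original, unaligned
nucleotide sequence byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .codes import GeneticCode, STANDARD_CODE, load_genetic_code
from .errors import InputError, InvalidColumnError

__all__ = [
    "NucSeq",
    "GAP_SITE",
    "GAP",
    "FRAMESHIFTED",
    "FULL",
    "classify_site",
    "site_aa",
    "pad_chunk",
    "EventRecord",
    "PairwiseAlignment",
    "MultipleAlignment",
]

GAP_SITE = "---"
GAP = "GAP"
FRAMESHIFTED = "FRAMESHIFTED"
FULL = "FULL"

_NT = set("ACGTN")
RELIABLE = "reliable"
LOWPEN = "lowpen"


@dataclass(frozen=True)
class NucSeq:
    """An input protein-coding nucleotide sequence.

    ``set_label`` selects which frameshift/stop penalties apply to the row
    (``"reliable"`` for trusted sequences, ``"lowpen"`` for pseudogenes or
    error-prone reads aligned with softer event costs); ``code_id`` is the
    NCBI translation table used to translate this sequence.
    """

    id: str
    residues: str
    set_label: str = RELIABLE
    code_id: int = 1

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("U", "T")
        if not norm:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(norm) - _NT
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains illegal characters: "
                + ", ".join(sorted(bad))
            )
        if self.set_label not in (RELIABLE, LOWPEN):
            raise InputError(f"unknown set label {self.set_label!r}")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def code(self) -> GeneticCode:
        return STANDARD_CODE if self.code_id == 1 else load_genetic_code(self.code_id)

    def with_residues(self, residues: str) -> "NucSeq":
        return replace(self, residues=residues)


def classify_site(site: str) -> str:
    """Classify a 3-character codon site; raises on invalid cells."""
    if len(site) != 3:
        raise InvalidColumnError(f"codon site must have 3 symbols, got {site!r}")
    if site == GAP_SITE:
        return GAP
    if "-" in site:
        raise InvalidColumnError(f"mixed gap site {site!r} is invalid")
    n_fs = site.count("!")
    if n_fs == 0:
        if set(site) - _NT:
            raise InvalidColumnError(f"illegal symbols in site {site!r}")
        return FULL
    if n_fs in (1, 2) and not (set(site) - _NT - {"!"}):
        return FRAMESHIFTED
    raise InvalidColumnError(f"invalid codon site {site!r}")


def site_aa(site: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Amino-acid view of one site: ``-`` for gaps, ``!`` for frameshifted
    sites, otherwise the translation (``*`` for stops, ``X`` for N-codons)."""
    kind = classify_site(site)
    if kind == GAP:
        return "-"
    if kind == FRAMESHIFTED:
        return "!"
    return code.translate_codon(site)


def pad_chunk(chunk: str) -> str:
    """Pad a 1-2 nt chunk with leading ``!`` into a frameshifted site."""
    if not 1 <= len(chunk) <= 3:
        raise InvalidColumnError(f"cannot make a codon site from {chunk!r}")
    return "!" * (3 - len(chunk)) + chunk


@dataclass(frozen=True)
class EventRecord:
    """One frameshift or internal-stop event of one aligned row.

    ``nt_position`` is 1-based on the original ungapped sequence;
    ``column`` is the 1-based codon-site index in the alignment.
    """

    seq_id: str
    event_type: str  # "frameshift" | "internal_stop"
    nt_position: int
    column: int


def _row_events(seq_id: str, sites: Sequence[str], code: GeneticCode) -> list[EventRecord]:
    content_cols = [c for c, s in enumerate(sites) if s != GAP_SITE]
    last_content = content_cols[-1] if content_cols else -1
    events: list[EventRecord] = []
    consumed = 0
    for c, site in enumerate(sites):
        kind = classify_site(site)
        if kind == GAP:
            continue
        if kind == FRAMESHIFTED:
            events.append(EventRecord(seq_id, "frameshift", consumed + 1, c + 1))
            consumed += 3 - site.count("!")
        else:
            if code.is_stop(site) and c != last_content:
                events.append(EventRecord(seq_id, "internal_stop", consumed + 1, c + 1))
            consumed += 3
    return events


class MultipleAlignment:
    """Rows of codon sites of equal column count, plus per-row metadata.

    Rows are keyed by sequence id; ``ids`` preserves a stable order.  The
    alignment never contains an all-gap column, and ungapping any row
    reproduces its input sequence exactly.
    """

    def __init__(
        self,
        ids: Sequence[str],
        rows: Mapping[str, Sequence[str]],
        set_labels: Mapping[str, str] | None = None,
        codes: Mapping[str, GeneticCode] | None = None,
        validate: bool = True,
    ) -> None:
        self.ids = list(ids)
        self.rows = {i: list(rows[i]) for i in self.ids}
        self.set_labels = {i: (set_labels or {}).get(i, RELIABLE) for i in self.ids}
        self.codes = {i: (codes or {}).get(i, STANDARD_CODE) for i in self.ids}
        if validate:
            self._validate()

    @classmethod
    def from_seq(cls, seq: NucSeq) -> "MultipleAlignment":
        """A single sequence as a 1-row alignment (frame-1 codon chunking;
        the trailing partial codon, if any, is ``!``-padded)."""
        sites = [seq.residues[i : i + 3] for i in range(0, len(seq.residues), 3)]
        if sites and len(sites[-1]) < 3:
            sites[-1] = pad_chunk(sites[-1])
        return cls(
            [seq.id],
            {seq.id: sites},
            {seq.id: seq.set_label},
            {seq.id: seq.code},
        )

    def _validate(self) -> None:
        if not self.ids:
            raise InputError("alignment has no rows")
        ncols = {len(r) for r in self.rows.values()}
        if len(ncols) != 1:
            raise InvalidColumnError("rows have unequal column counts")
        for sites in self.rows.values():
            for s in sites:
                classify_site(s)
        for c in range(self.ncols):
            if all(self.rows[i][c] == GAP_SITE for i in self.ids):
                raise InvalidColumnError(f"all-gap column at index {c}")

    @property
    def ncols(self) -> int:
        return len(self.rows[self.ids[0]])

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> list[str]:
        return self.rows[seq_id]

    def nt_row(self, seq_id: str) -> str:
        return "".join(self.rows[seq_id])

    def aa_row(self, seq_id: str) -> str:
        code = self.codes[seq_id]
        return "".join(site_aa(s, code) for s in self.rows[seq_id])

    def ungapped(self, seq_id: str) -> str:
        return self.nt_row(seq_id).replace("-", "").replace("!", "")

    def to_nucseq(self, seq_id: str) -> NucSeq:
        return NucSeq(
            seq_id,
            self.ungapped(seq_id),
            self.set_labels[seq_id],
            self.codes[seq_id].table_id,
        )

    def induced_pair(self, id_a: str, id_b: str) -> tuple[list[str], list[str]]:
        """The pairwise alignment induced on two rows (dual-gap columns
        dropped)."""
        ra, rb = self.rows[id_a], self.rows[id_b]
        keep = [(a, b) for a, b in zip(ra, rb) if not (a == GAP_SITE and b == GAP_SITE)]
        return [a for a, _ in keep], [b for _, b in keep]

    def subset(self, keep_ids: Iterable[str]) -> "MultipleAlignment":
        """Restriction to a subset of rows, dropping all-gap columns."""
        keep = [i for i in self.ids if i in set(keep_ids)]
        if not keep:
            raise InputError("subset would be empty")
        cols = [
            c
            for c in range(self.ncols)
            if any(self.rows[i][c] != GAP_SITE for i in keep)
        ]
        rows = {i: [self.rows[i][c] for c in cols] for i in keep}
        return MultipleAlignment(
            keep, rows, self.set_labels, self.codes, validate=False
        )

    def reordered(self, order: Sequence[str]) -> "MultipleAlignment":
        if set(order) != set(self.ids):
            raise InputError("reorder id set mismatch")
        return MultipleAlignment(
            list(order), self.rows, self.set_labels, self.codes, validate=False
        )

    def events(self) -> list[EventRecord]:
        out: list[EventRecord] = []
        for i in sorted(self.ids):
            out.extend(_row_events(i, self.rows[i], self.codes[i]))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        return self.ids == other.ids and self.rows == other.rows

    def __repr__(self) -> str:
        return f"<MultipleAlignment rows={len(self.ids)} cols={self.ncols}>"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored two-row alignment plus the per-row event lists."""

    id_a: str
    id_b: str
    sites_a: tuple[str, ...]
    sites_b: tuple[str, ...]
    score: int
    events: tuple[EventRecord, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.sites_a) != len(self.sites_b):
            raise InvalidColumnError("pairwise rows have unequal column counts")

    def to_msa(
        self,
        set_labels: Mapping[str, str] | None = None,
        codes: Mapping[str, GeneticCode] | None = None,
    ) -> MultipleAlignment:
        return MultipleAlignment(
            [self.id_a, self.id_b],
            {self.id_a: self.sites_a, self.id_b: self.sites_b},
            set_labels,
            codes,
        )
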