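"""Genetic codes and frame-1 raw translation.

Codon tables follow the NCBI numbering and are taken from Biopython's
``Bio.Data.CodonTable``; a :class:`GeneticCode` holds the full 64-entry map
from DNA triplets to amino-acid symbols, with ``*`` marking stop codons.

Raw translation never interrupts at a stop: internal stops become ``*`` in
the amino-acid string, a trailing partial codon becomes ``!`` and any codon
containing an ``N`` becomes ``X``.  This is the translation view used by the
frameshift-aware alignment objective, where reading simply continues across
ORF-disrupting events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable

from .errors import ConfigError

__all__ = ["GeneticCode", "load_genetic_code", "translate_raw", "STANDARD_CODE"]

_BASES = "TCAG"


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table as a total map over the 64 DNA triplets."""

    table_id: int
    codon_map: Mapping[str, str]
    stop_codons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ConfigError(
                f"genetic code table {self.table_id} does not cover all 64 codons"
            )
        stops = tuple(sorted(c for c, aa in self.codon_map.items() if aa == "*"))
        if not stops:
            raise ConfigError(f"genetic code table {self.table_id} has no stop codon")
        object.__setattr__(self, "stop_codons", stops)

    def translate_codon(self, codon: str) -> str:
        """Translate one triplet; ``N``-containing codons give ``X``,
        triplets with fewer than 3 nucleotides give ``!``."""
        if len(codon) != 3 or "!" in codon:
            return "!"
        if "N" in codon:
            return "X"
        try:
            return self.codon_map[codon]
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise ConfigError(f"cannot translate codon {codon!r}") from exc

    def is_stop(self, codon: str) -> bool:
        return len(codon) == 3 and "N" not in codon and self.codon_map.get(codon) == "*"


def load_genetic_code(table_id: int) -> GeneticCode:
    """Return the :class:`GeneticCode` for an NCBI translation-table number.

    Tables 1 (standard), 2 (vertebrate mitochondrial), 5 and 11 are
    guaranteed; any table shipped with Biopython works.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[int(table_id)]
    except KeyError:
        raise ConfigError(f"unsupported genetic code table: {table_id}") from None
    codon_map = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    codon_map[codon] = "*"
                else:
                    codon_map[codon] = table.forward_table[codon]
    return GeneticCode(table_id=int(table_id), codon_map=codon_map)


STANDARD_CODE = load_genetic_code(1)


def translate_raw(seq, code: GeneticCode = STANDARD_CODE) -> str:
    """Frame-1 translation of a nucleotide sequence, ceil(len/3) symbols long.

    Accepts a :class:`~orfalign.model.NucSeq` or a plain string.  Stops do not
    interrupt translation; the trailing partial codon (if any) yields ``!``.
    """
    residues = getattr(seq, "residues", seq)
    out = []
    for i in range(0, len(residues), 3):
        out.append(code.translate_codon(residues[i : i + 3]))
    return "".join(out)
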