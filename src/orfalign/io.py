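"""FASTA input, dual NT/AA aligned output, event reports, code files.

The aligner writes the same alignment twice: ``<prefix>_NT.fasta`` with
rows as concatenated codon sites (nucleotides, ``!`` for frameshift
padding, ``-`` for gaps) and ``<prefix>_AA.fasta`` with one symbol per
codon site (residue, ``*`` for stops, ``!`` for frameshifted sites, ``-``
for gaps); each NT row is exactly three times its AA row.  Events are
reported as a tab-separated table, one line per frameshifted site and per
internal stop.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import GeneticCode, load_genetic_code
from .errors import InputError
from .model import EventRecord, MultipleAlignment, NucSeq

__all__ = [
    "read_fasta",
    "write_alignment",
    "read_alignment_fasta",
    "report_events",
    "write_events",
    "read_code_file",
]


def read_fasta(
    path,
    set_label: str = "reliable",
    default_code: int = 1,
    code_ids: Mapping[str, int] | None = None,
) -> list[NucSeq]:
    """Read unaligned coding sequences; ids are the header up to the first
    whitespace, residues are uppercased with U normalised to T."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read FASTA file {path}")
    seqs: list[NucSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        code_id = (code_ids or {}).get(rec.id, default_code)
        seqs.append(NucSeq(rec.id, str(rec.seq), set_label, code_id))
    if not seqs:
        raise InputError(f"no FASTA records in {path}")
    return seqs


def write_alignment(A: MultipleAlignment, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>_NT.fasta`` and ``<prefix>_AA.fasta``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nt_path = prefix.parent / (prefix.name + "_NT.fasta")
    aa_path = prefix.parent / (prefix.name + "_AA.fasta")
    nt_recs = [SeqRecord(Seq(A.nt_row(i)), id=i, description="") for i in A.ids]
    aa_recs = [SeqRecord(Seq(A.aa_row(i)), id=i, description="") for i in A.ids]
    SeqIO.write(nt_recs, str(nt_path), "fasta")
    SeqIO.write(aa_recs, str(aa_path), "fasta")
    return nt_path, aa_path


def read_alignment_fasta(
    path,
    set_labels: Mapping[str, str] | None = None,
    code_ids: Mapping[str, int] | None = None,
) -> MultipleAlignment:
    """Read an NT-level aligned FASTA (as written by
    :func:`write_alignment`) back into a :class:`MultipleAlignment`."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read FASTA file {path}")
    ids: list[str] = []
    rows: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        s = str(rec.seq).upper().replace("U", "T")
        if len(s) % 3:
            raise InputError(
                f"aligned row {rec.id!r} has length {len(s)}, not a multiple of 3"
            )
        ids.append(rec.id)
        rows[rec.id] = [s[i : i + 3] for i in range(0, len(s), 3)]
    if not ids:
        raise InputError(f"no FASTA records in {path}")
    codes: dict[str, GeneticCode] = {
        i: load_genetic_code((code_ids or {}).get(i, 1)) for i in ids
    }
    return MultipleAlignment(ids, rows, set_labels, codes)


def report_events(A: MultipleAlignment) -> list[EventRecord]:
    """One record per frameshifted site and per internal stop, sorted by
    (id, position); terminal stops are exempt and never reported."""
    return A.events()


def write_events(events: Sequence[EventRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence_id", "event_type", "nt_position", "codon_column"])
        for e in events:
            w.writerow([e.seq_id, e.event_type, e.nt_position, e.column])
    return path


def read_code_file(path) -> dict[str, int]:
    """Two-column, tab-separated ``sequence_id <TAB> table_id`` assignment
    file; unlisted sequences keep the default table."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected 'id<TAB>table_id'")
            try:
                out[parts[0]] = int(parts[1])
            except ValueError:
                raise InputError(f"{path}:{ln}: table id {parts[1]!r} is not an integer")
    return out
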