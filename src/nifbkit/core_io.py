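"""Sequence and taxonomy I/O.

Every pipeline stage consumes :class:`ProteinRecord` objects read from plain
FASTA, optionally joined against a tab-separated taxonomy table that maps
record identifiers to a superkingdom (Bacteria or Archaea) and a free-text
phylum/class label.  Parsing is strict: the residue alphabet is the twenty
canonical amino acids plus ``X`` for an unknown residue, and ambiguity codes
(``B``, ``Z``, ``J``, ``U``, ``O``) are rejected so that downstream motif
semantics stay well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue alphabet accepted throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Accepted superkingdom labels for taxonomy rows.
SUPERKINGDOMS = ("Bacteria", "Archaea")

#: Default FASTA line width.
FASTA_WRAP = 60


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate protein sequence flowing through the pipeline."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"invalid residue {sorted(bad)!r} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic assignment of one protein record."""

    record_id: str
    superkingdom: str
    group: str

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"invalid superkingdom {self.superkingdom!r} for "
                f"{self.record_id!r} (expected one of {SUPERKINGDOMS})"
            )


def _record_from_seqio(rec: SeqRecord) -> ProteinRecord:
    seq = str(rec.seq).upper().rstrip("*")
    desc = rec.description
    # SeqIO repeats the id at the start of the description; keep the remainder.
    if desc.startswith(rec.id):
        desc = desc[len(rec.id):].strip()
    return ProteinRecord(id=rec.id, sequence=seq, description=desc)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased and trailing ``*`` terminators stripped; record
    order is preserved.  Raises ``ValueError`` on an empty file, duplicate
    identifiers, or residues outside the accepted alphabet.
    """
    records = [_record_from_seqio(r) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no records in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def write_fasta(
    records: Sequence[ProteinRecord], path: str | Path, wrap: int = FASTA_WRAP
) -> None:
    """Write records as FASTA with ``wrap``-column sequence lines."""
    if not records:
        raise ValueError("nothing to write")
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file as ``(id, aligned sequence)`` pairs.

    Unlike :func:`read_fasta` this keeps gap characters; residues are still
    uppercased.
    """
    rows = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no records in {path}")
    return rows


_TAXONOMY_COLUMNS = ("record_id", "superkingdom", "group")


def read_taxonomy(path: str | Path) -> list[TaxonomyRecord]:
    """Read a taxonomy table (TSV with header record_id/superkingdom/group)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"malformed taxonomy table: {path} is empty")
    header = tuple(lines[0].split("\t"))
    if header[: len(_TAXONOMY_COLUMNS)] != _TAXONOMY_COLUMNS:
        raise ValueError(
            f"malformed taxonomy table: expected columns {_TAXONOMY_COLUMNS}, "
            f"got {header}"
        )
    out: list[TaxonomyRecord] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed taxonomy table: short row {ln!r}")
        out.append(TaxonomyRecord(parts[0], parts[1], parts[2]))
    return out


@dataclass
class TaxonomyJoin:
    """Result of joining protein records with a taxonomy table."""

    mapping: dict[str, TaxonomyRecord]
    unmapped_records: list[str] = field(default_factory=list)
    orphan_taxonomy_rows: list[str] = field(default_factory=list)


def join_taxonomy(
    records: Iterable[ProteinRecord], taxonomy: Iterable[TaxonomyRecord]
) -> TaxonomyJoin:
    """Join records to taxonomy rows by identifier.

    Records without a taxonomy row are reported in ``unmapped_records`` (not
    an error); taxonomy rows referencing no sequence are reported in
    ``orphan_taxonomy_rows``.
    """
    by_id = {t.record_id: t for t in taxonomy}
    record_ids = [r.id for r in records]
    mapping = {rid: by_id[rid] for rid in record_ids if rid in by_id}
    unmapped = [rid for rid in record_ids if rid not in by_id]
    orphans = [rid for rid in by_id if rid not in set(record_ids)]
    return TaxonomyJoin(mapping=mapping, unmapped_records=unmapped,
                        orphan_taxonomy_rows=orphans)


def records_to_seqrecords(records: Iterable[ProteinRecord]) -> list[SeqRecord]:
    """Convert to Biopython records (helper for interop)."""
    return [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
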