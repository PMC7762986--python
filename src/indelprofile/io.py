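"""Readers and writers for aligned FASTA and the pipeline's tabular formats.

Conventions used throughout the package:

* alignment coordinates are 0-based, half-open columns;
* the only gap character is ``'-'`` ('.' is rejected so length counting
  stays unambiguous);
* tabular files are TSV with '.' as decimal separator; missing cells are
  the literal string ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentWidthError,
    DuplicateKeyError,
    EmptyInputError,
    GapDialectError,
    SchemaError,
)

logger = logging.getLogger(__name__)

GAP = "-"
CANONICAL_RESIDUES = frozenset("ACGTN-")

__all__ = [
    "Alignment",
    "MetadataRecord",
    "SampleMetadata",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "read_profile_table",
    "write_profile_table",
    "unusual_residues",
]


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment for a single marker.

    Parameters
    ----------
    marker_name:
        Identifier of the marker (e.g. an intergenic-spacer name).
    sequences:
        Ordered ``(sequence_id, residues)`` pairs. All residue strings
        must have identical length and ids must be unique.
    """

    marker_name: str
    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError(f"alignment {self.marker_name!r} has no sequences")
        width = len(self.sequences[0][1])
        if width == 0:
            raise AlignmentWidthError(
                f"alignment {self.marker_name!r} has zero columns"
            )
        for seq_id, residues in self.sequences:
            if len(residues) != width:
                raise AlignmentWidthError(
                    f"record {seq_id!r} has {len(residues)} columns, "
                    f"expected {width}"
                )
        ids = [s for s, _ in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateKeyError(
                f"duplicate sequence ids in {self.marker_name!r}: {dupes}"
            )

    @property
    def width(self) -> int:
        return len(self.sequences[0][1])

    @property
    def ids(self) -> list[str]:
        return [s for s, _ in self.sequences]

    def residues(self, sequence_id: str) -> str:
        for seq_id, res in self.sequences:
            if seq_id == sequence_id:
                return res
        raise KeyError(sequence_id)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class MetadataRecord:
    sequence_id: str
    accession: str
    species: str
    subspecies: Optional[str]
    marker: str


@dataclass
class SampleMetadata:
    """Validated sample metadata: one record per (sequence_id, marker)."""

    records: list[MetadataRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.sequence_id, r.marker) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DuplicateKeyError(f"duplicate (sequence_id, marker) keys: {dupes}")

    def for_marker(self, marker: str) -> dict[str, MetadataRecord]:
        return {r.sequence_id: r for r in self.records if r.marker == marker}

    @property
    def accessions(self) -> list[str]:
        return sorted({r.accession for r in self.records})

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})


def _normalize_residues(seq_id: str, raw: str) -> str:
    residues = str(raw).upper()
    if "." in residues:
        raise GapDialectError(
            f"record {seq_id!r} uses '.' as gap; only '-' is accepted"
        )
    return residues


def unusual_residues(aln: Alignment) -> dict[str, set[str]]:
    """Report characters outside {A,C,G,T,N,-} per sequence (IUPAC codes etc.)."""
    report: dict[str, set[str]] = {}
    for seq_id, residues in aln.sequences:
        odd = set(residues) - CANONICAL_RESIDUES
        if odd:
            report[seq_id] = odd
    return report


def read_alignment(path: str | Path, marker_name: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Residues are upper-cased; records must all have the same length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    sequences = tuple(
        (rec.id, _normalize_residues(rec.id, str(rec.seq))) for rec in records
    )
    aln = Alignment(marker_name=marker_name, sequences=sequences)
    odd = unusual_residues(aln)
    if odd:
        logger.warning(
            "alignment %s: non-canonical residues in %d record(s): %s",
            marker_name,
            len(odd),
            {k: sorted(v) for k, v in sorted(odd.items())},
        )
    return aln


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, residues in aln.sequences:
            fh.write(f">{seq_id}\n{residues}\n")


_META_COLUMNS = ["sequence_id", "accession", "species", "subspecies", "marker"]


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample metadata TSV (sequence_id, accession, species, subspecies, marker)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"metadata file {path} is empty") from exc
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file {path} missing column(s): {missing}")
    if df.empty:
        raise SchemaError(f"metadata file {path} has no rows")
    records = [
        MetadataRecord(
            sequence_id=row.sequence_id,
            accession=row.accession,
            species=row.species,
            subspecies=None if pd.isna(row.subspecies) else row.subspecies,
            marker=row.marker,
        )
        for row in df.itertuples()
    ]
    return SampleMetadata(records=records)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    rows = [
        {
            "sequence_id": r.sequence_id,
            "accession": r.accession,
            "species": r.species,
            "subspecies": "" if r.subspecies is None else r.subspecies,
            "marker": r.marker,
        }
        for r in meta.records
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def write_profile_table(table, path: str | Path) -> None:
    """Write a profile table as TSV: accession, species, one column per region.

    Missing lengths are written as the literal ``NA``; round-trips
    losslessly with :func:`read_profile_table`.
    """
    from .profiler import ProfileTable  # local import avoids a cycle

    if not isinstance(table, ProfileTable):  # pragma: no cover - defensive
        raise TypeError("expected a ProfileTable")
    if not table.rows:
        raise EmptyInputError("refusing to write an empty profile table")
    with open(path, "w") as fh:
        fh.write("\t".join(["accession", "species", *table.panel]) + "\n")
        for row in table.rows:
            cells = ["NA" if v is None else str(int(v)) for v in row.lengths]
            fh.write("\t".join([row.accession, row.species, *cells]) + "\n")


def read_profile_table(path: str | Path):
    """Read a profile table written by :func:`write_profile_table`."""
    from .profiler import ProfileRow, ProfileTable

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"profile table {path} is empty") from exc
    for col in ("accession", "species"):
        if col not in df.columns:
            raise SchemaError(f"profile table {path} missing column {col!r}")
    panel = [c for c in df.columns if c not in ("accession", "species")]
    if not panel:
        raise SchemaError(f"profile table {path} has no region columns")
    rows = []
    for _, rec in df.iterrows():
        lengths = tuple(
            None if (pd.isna(rec[c]) or rec[c] == "NA") else int(rec[c])
            for c in panel
        )
        rows.append(
            ProfileRow(
                accession=rec["accession"], species=rec["species"], lengths=lengths
            )
        )
    return ProfileTable(panel=panel, rows=rows)
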