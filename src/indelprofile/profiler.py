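"""Numeric length profiles: ungapped fragment lengths per hypervariable region.

Lengths are counts of non-gap characters inside the region's alignment
span — not alignment-column spans, which would be constant across
sequences. 'N' counts as a residue: ambiguity does not change the
physical fragment length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import (
    GeometryError,
    LabelingError,
    MetadataConflictError,
    ParameterError,
)
from .io import GAP, Alignment, SampleMetadata
from .regions import HypervariableRegion

__all__ = [
    "ProfileRow",
    "ProfileTable",
    "fragment_length",
    "build_profiles",
    "merge_panels",
    "marker_of_label",
]


@dataclass(frozen=True)
class ProfileRow:
    """One accession's length profile; ``None`` marks a missing length."""

    accession: str
    species: str
    lengths: tuple[Optional[int], ...]

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.lengths)


@dataclass
class ProfileTable:
    """Accession x region matrix of ungapped fragment lengths."""

    panel: list[str]
    rows: list[ProfileRow]

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row.lengths) != len(self.panel):
                raise ParameterError(
                    f"row {row.accession!r} has {len(row.lengths)} lengths for a "
                    f"{len(self.panel)}-region panel"
                )
            if not row.species:
                raise ParameterError(f"row {row.accession!r} has empty species label")

    def restrict(self, positions: Sequence[int]) -> "ProfileTable":
        """A new table keeping only the given panel positions, in given order."""
        positions = list(positions)
        for p in positions:
            if not (0 <= p < len(self.panel)):
                raise ParameterError(f"panel position {p} out of range")
        return ProfileTable(
            panel=[self.panel[p] for p in positions],
            rows=[
                ProfileRow(
                    accession=r.accession,
                    species=r.species,
                    lengths=tuple(r.lengths[p] for p in positions),
                )
                for r in self.rows
            ],
        )

    def rename_panel(self, labels: Sequence[str]) -> "ProfileTable":
        if len(labels) != len(self.panel):
            raise ParameterError("label count does not match panel size")
        return ProfileTable(panel=list(labels), rows=list(self.rows))

    def complete_rows(self) -> list[ProfileRow]:
        return [r for r in self.rows if r.complete]

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.rows})


def marker_of_label(label: str) -> str:
    """Marker name encoded in a panel label of the form ``marker:hv<i>``."""
    return label.split(":", 1)[0]


def fragment_length(residues: str, region: HypervariableRegion) -> int:
    """Count non-gap characters of a gapped sequence inside a region span."""
    if region.end > len(residues):
        raise GeometryError(
            f"region [{region.start},{region.end}) exceeds sequence length "
            f"{len(residues)}"
        )
    span = residues[region.start : region.end]
    return len(span) - span.count(GAP)


def build_profiles(
    aln: Alignment,
    hv_regions: list[HypervariableRegion],
    meta: SampleMetadata,
    taxon_level: str = "species",
) -> ProfileTable:
    """Length profiles for every sequence of one marker alignment.

    Rows are keyed by accession and sorted by accession; regions are
    ordered by their ``hv_index``. With ``taxon_level='subspecies'`` the
    species label becomes ``species/subspecies`` so subspecies are
    treated as terminal taxa.

    Duplicate sequences for one accession are collapsed when their
    profiles agree and rejected otherwise.
    """
    if taxon_level not in ("species", "subspecies"):
        raise ParameterError(f"unknown taxon_level {taxon_level!r}")
    regions = sorted(hv_regions, key=lambda r: r.hv_index)
    lookup = meta.for_marker(aln.marker_name)
    by_accession: dict[str, ProfileRow] = {}
    for seq_id, residues in aln.sequences:
        rec = lookup.get(seq_id)
        if rec is None:
            raise LabelingError(
                f"sequence {seq_id!r} has no metadata for marker "
                f"{aln.marker_name!r}"
            )
        species = rec.species
        if taxon_level == "subspecies" and rec.subspecies:
            species = f"{rec.species}/{rec.subspecies}"
        lengths = tuple(fragment_length(residues, r) for r in regions)
        row = ProfileRow(accession=rec.accession, species=species, lengths=lengths)
        prev = by_accession.get(rec.accession)
        if prev is not None:
            if prev.lengths != row.lengths or prev.species != row.species:
                raise MetadataConflictError(
                    f"accession {rec.accession!r} has conflicting duplicate "
                    f"profiles for marker {aln.marker_name!r}"
                )
            continue
        by_accession[rec.accession] = row
    return ProfileTable(
        panel=[r.label for r in regions],
        rows=[by_accession[a] for a in sorted(by_accession)],
    )


def merge_panels(tables: list[ProfileTable]) -> ProfileTable:
    """Concatenate per-marker panels into one multi-marker profile table.

    The merged panel is the concatenation of the input panels in the
    given order; accessions absent from a table get missing entries for
    that table's columns. A conflicting species label for one accession
    across tables is an error.
    """
    if not tables:
        raise ParameterError("merge_panels needs at least one table")
    panel: list[str] = []
    for t in tables:
        panel.extend(t.panel)
    if len(set(panel)) != len(panel):
        dupes = sorted({c for c in panel if panel.count(c) > 1})
        raise ParameterError(
            f"duplicate panel labels across tables: {dupes}; "
            "rename panels before merging"
        )
    species_of: dict[str, str] = {}
    for t in tables:
        for row in t.rows:
            known = species_of.get(row.accession)
            if known is None:
                species_of[row.accession] = row.species
            elif known != row.species:
                raise MetadataConflictError(
                    f"accession {row.accession!r} labeled {known!r} and "
                    f"{row.species!r} in different tables"
                )
    rows: list[ProfileRow] = []
    for accession in sorted(species_of):
        lengths: list[Optional[int]] = []
        for t in tables:
            match = next((r for r in t.rows if r.accession == accession), None)
            if match is None:
                lengths.extend([None] * len(t.panel))
            else:
                lengths.extend(match.lengths)
        rows.append(
            ProfileRow(
                accession=accession,
                species=species_of[accession],
                lengths=tuple(lengths),
            )
        )
    return ProfileTable(panel=panel, rows=rows)
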