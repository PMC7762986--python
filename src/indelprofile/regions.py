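"""Conserved anchor blocks and the hypervariable regions between them.

A conserved region is a maximal run of alignment columns that are
(near-)identical and (near-)gap-free; the spans between consecutive
conserved blocks are the hypervariable regions whose ungapped lengths
carry the identification signal. Spans outside the first/last block are
flagged *peripheral* and excluded from concatenated analyses by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import GeometryError, ParameterError, SchemaError
from .io import GAP, Alignment

__all__ = [
    "ConservedRegion",
    "HypervariableRegion",
    "detect_conserved_regions",
    "derive_hypervariable_regions",
    "read_regions",
    "write_regions",
]

PERIPHERAL_SUFFIX = "~p"


@dataclass(frozen=True)
class ConservedRegion:
    """A conserved anchor block, 0-based half-open alignment columns."""

    marker_name: str
    region_index: int
    start: int
    end: int
    consensus: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GeometryError(
                f"conserved region {self.marker_name}:{self.region_index} has "
                f"invalid span [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HypervariableRegion:
    """A length-variable span between anchors (or outside them when peripheral)."""

    marker_name: str
    hv_index: int
    start: int
    end: int
    peripheral: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise GeometryError(
                f"hypervariable region {self.marker_name}:{self.hv_index} has "
                f"invalid span [{self.start}, {self.end})"
            )

    @property
    def label(self) -> str:
        suffix = PERIPHERAL_SUFFIX if self.peripheral else ""
        return f"{self.marker_name}:hv{self.hv_index}{suffix}"


def _column(aln: Alignment, j: int) -> list[str]:
    return [residues[j] for _, residues in aln.sequences]


def _qualify_column(col: list[str], min_identity: float, max_gap_fraction: float):
    """Return (qualifies, modal_residue) for one alignment column."""
    n = len(col)
    gaps = col.count(GAP)
    non_gap = [c for c in col if c != GAP]
    if not non_gap:
        return False, GAP
    counts = Counter(non_gap)
    top = max(counts.values())
    # ties broken alphabetically for a deterministic consensus
    modal = min(c for c, k in counts.items() if k == top)
    ok = (gaps / n) <= max_gap_fraction and (top / len(non_gap)) >= min_identity
    return ok, modal


def detect_conserved_regions(
    aln: Alignment,
    window: int = 1,
    min_identity: float = 1.0,
    max_gap_fraction: float = 0.0,
    min_width: int = 15,
) -> list[ConservedRegion]:
    """Find maximal runs of conserved columns of length >= ``min_width``.

    A column qualifies when its gap fraction is <= ``max_gap_fraction``
    and the modal residue among non-gap characters has frequency
    >= ``min_identity``. With ``window`` > 1, only runs of qualifying
    columns at least ``window`` long are considered at all.

    Returns regions left to right; an empty list when nothing qualifies.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if window > aln.width:
        raise ParameterError(
            f"window ({window}) exceeds alignment width ({aln.width})"
        )
    if not (0.0 < min_identity <= 1.0):
        raise ParameterError(f"min_identity must be in (0, 1], got {min_identity}")
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise ParameterError(
            f"max_gap_fraction must be in [0, 1], got {max_gap_fraction}"
        )
    if min_width < 1:
        raise ParameterError(f"min_width must be >= 1, got {min_width}")

    flags: list[bool] = []
    modal: list[str] = []
    for j in range(aln.width):
        ok, m = _qualify_column(_column(aln, j), min_identity, max_gap_fraction)
        flags.append(ok)
        modal.append(m)

    regions: list[ConservedRegion] = []
    j = 0
    idx = 0
    min_run = max(min_width, window)
    while j < aln.width:
        if not flags[j]:
            j += 1
            continue
        start = j
        while j < aln.width and flags[j]:
            j += 1
        if j - start >= min_run:
            regions.append(
                ConservedRegion(
                    marker_name=aln.marker_name,
                    region_index=idx,
                    start=start,
                    end=j,
                    consensus="".join(modal[start:j]),
                )
            )
            idx += 1
    return regions


def _check_sorted_disjoint(regions: list[ConservedRegion]) -> None:
    for a, b in zip(regions, regions[1:]):
        if b.start < a.end:
            raise GeometryError(
                f"conserved regions overlap: [{a.start},{a.end}) and "
                f"[{b.start},{b.end}) in {a.marker_name!r}"
            )


def derive_hypervariable_regions(
    regions: list[ConservedRegion],
    aln_width: int,
    include_peripheral: bool = False,
) -> list[HypervariableRegion]:
    """Spans between consecutive conserved blocks (k blocks -> k-1 interior).

    When ``include_peripheral`` the (possibly empty) spans before the
    first and after the last block are also returned, flagged peripheral.
    """
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: r.start)
    _check_sorted_disjoint(regions)
    if regions[-1].end > aln_width:
        raise GeometryError(
            f"conserved region ends at {regions[-1].end} beyond width {aln_width}"
        )
    marker = regions[0].marker_name
    out: list[HypervariableRegion] = []
    idx = 0
    if include_peripheral:
        out.append(
            HypervariableRegion(marker, idx, 0, regions[0].start, peripheral=True)
        )
        idx += 1
    for a, b in zip(regions, regions[1:]):
        out.append(HypervariableRegion(marker, idx, a.end, b.start))
        idx += 1
    if include_peripheral:
        out.append(
            HypervariableRegion(
                marker, idx, regions[-1].end, aln_width, peripheral=True
            )
        )
    return out


_REGION_COLUMNS = ["marker", "region_index", "start", "end", "consensus"]


def write_regions(regions: list[ConservedRegion], path: str | Path) -> None:
    """Write conserved regions as TSV (0-based half-open columns)."""
    rows = [
        {
            "marker": r.marker_name,
            "region_index": r.region_index,
            "start": r.start,
            "end": r.end,
            "consensus": r.consensus,
        }
        for r in regions
    ]
    pd.DataFrame(rows, columns=_REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[ConservedRegion]:
    """Read a regions TSV; rows are sorted per marker and checked for overlap."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"marker": str, "consensus": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"regions file {path} is empty") from exc
    missing = [c for c in _REGION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"regions file {path} missing column(s): {missing}")
    regions: list[ConservedRegion] = []
    for marker, group in df.groupby("marker", sort=True):
        group = group.sort_values("start")
        marker_regions = [
            ConservedRegion(
                marker_name=str(marker),
                region_index=i,
                start=int(row.start),
                end=int(row.end),
                consensus="" if pd.isna(row.consensus) else str(row.consensus),
            )
            for i, row in enumerate(group.itertuples())
        ]
        _check_sorted_disjoint(marker_regions)
        regions.extend(marker_regions)
    return regions
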