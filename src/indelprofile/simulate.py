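"""Synthetic marker alignments with known ground truth.

Each simulated marker is a set of identical, gap-free anchor blocks
flanking hypervariable segments whose ungapped lengths carry a
per-species effect plus optional intraspecific indel noise. Segments are
left-aligned and right-padded with gaps, so anchors occupy identical
columns in every sequence and strict conserved-region detection recovers
them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .io import (
    Alignment,
    MetadataRecord,
    SampleMetadata,
    write_alignment,
    write_metadata,
    write_profile_table,
)
from .profiler import ProfileRow, ProfileTable
from .regions import ConservedRegion, write_regions

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "default_allocation",
    "simulate",
    "truth_profiles",
    "write_simulation",
]

ALPHABET = np.array(list("ACGT"))


def default_allocation(n_species: int = 13, n_accessions: int = 35) -> list[int]:
    """Accessions per species, sizes as even as possible (2-3 for 35/13)."""
    if n_species < 1 or n_accessions < n_species:
        raise ConfigError("need at least one accession per species")
    base = n_accessions // n_species
    extra = n_accessions % n_species
    return [base + 1] * extra + [base] * (n_species - extra)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic data set.

    ``accessions_per_species`` may be a single integer or an explicit
    per-species allocation. ``distinct_species_effects`` draws the
    per-region species effects without replacement, guaranteeing that
    species profiles differ whenever intraspecific noise is off.
    """

    n_species: int = 13
    accessions_per_species: int | Sequence[int] = field(
        default_factory=lambda: default_allocation(13, 35)
    )
    n_markers: int = 4
    conserved_blocks_per_marker: int = 4
    conserved_block_length: int = 20
    hv_base_length_range: tuple[int, int] = (30, 60)
    species_length_effect_range: tuple[int, int] = (-8, 8)
    intraspecific_indel_prob: float = 0.0
    intraspecific_indel_size_range: tuple[int, int] = (1, 3)
    missing_prob: float = 0.0
    seed: int = 0
    distinct_species_effects: bool = True
    marker_prefix: str = "marker"

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if isinstance(self.accessions_per_species, int):
            if self.accessions_per_species < 1:
                raise ConfigError("accessions_per_species must be >= 1")
            self.accessions_per_species = [
                self.accessions_per_species
            ] * self.n_species
        else:
            self.accessions_per_species = list(self.accessions_per_species)
        if len(self.accessions_per_species) != self.n_species:
            raise ConfigError(
                "accessions_per_species allocation must have n_species entries"
            )
        if any(a < 1 for a in self.accessions_per_species):
            raise ConfigError("every species needs >= 1 accession")
        if self.n_markers < 1 or self.conserved_blocks_per_marker < 2:
            raise ConfigError("need >= 1 marker and >= 2 conserved blocks")
        if self.conserved_block_length < 1:
            raise ConfigError("conserved_block_length must be >= 1")
        for name in (
            "hv_base_length_range",
            "species_length_effect_range",
            "intraspecific_indel_size_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} is not ordered: ({lo}, {hi})")
            setattr(self, name, (int(lo), int(hi)))
        for name in ("intraspecific_indel_prob", "missing_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.hv_base_length_range[0] + self.species_length_effect_range[0] < 0:
            raise ConfigError(
                "minimum base length plus most negative species effect is "
                "negative; fragment lengths could go below zero"
            )
        if self.distinct_species_effects:
            span = (
                self.species_length_effect_range[1]
                - self.species_length_effect_range[0]
                + 1
            )
            if span < self.n_species:
                raise ConfigError(
                    "species_length_effect_range too narrow for distinct "
                    f"effects across {self.n_species} species"
                )

    @property
    def n_accessions(self) -> int:
        return int(sum(self.accessions_per_species))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        for key in (
            "hv_base_length_range",
            "species_length_effect_range",
            "intraspecific_indel_size_range",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"unknown config key: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "accessions_per_species": list(self.accessions_per_species),
            "n_markers": self.n_markers,
            "conserved_blocks_per_marker": self.conserved_blocks_per_marker,
            "conserved_block_length": self.conserved_block_length,
            "hv_base_length_range": list(self.hv_base_length_range),
            "species_length_effect_range": list(self.species_length_effect_range),
            "intraspecific_indel_prob": self.intraspecific_indel_prob,
            "intraspecific_indel_size_range": list(
                self.intraspecific_indel_size_range
            ),
            "missing_prob": self.missing_prob,
            "seed": self.seed,
            "distinct_species_effects": self.distinct_species_effects,
            "marker_prefix": self.marker_prefix,
        }


@dataclass
class GroundTruth:
    """Planted truth for every stage of the pipeline."""

    anchor_intervals: dict[str, list[tuple[int, int]]]
    fragment_lengths: dict[tuple[str, str], tuple[int, ...]]
    species_assignment: dict[str, str]
    markers: list[str]


@dataclass
class SimulationResult:
    alignments: dict[str, Alignment]
    metadata: SampleMetadata
    truth: GroundTruth
    config: SimulationConfig


def _random_seq(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return "".join(ALPHABET[rng.integers(0, 4, size=length)])


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate alignments, metadata and ground truth from a config.

    Fully reproducible: all randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    species = [f"sp{idx + 1:02d}" for idx in range(config.n_species)]
    accessions: list[tuple[str, str]] = []  # (accession, species)
    acc_idx = 0
    for sp, count in zip(species, config.accessions_per_species):
        for _ in range(count):
            acc_idx += 1
            accessions.append((f"acc{acc_idx:03d}", sp))

    markers = [f"{config.marker_prefix}{m + 1:02d}" for m in range(config.n_markers)]
    n_hv = config.conserved_blocks_per_marker - 1
    lo_b, hi_b = config.hv_base_length_range
    lo_e, hi_e = config.species_length_effect_range
    lo_s, hi_s = config.intraspecific_indel_size_range

    alignments: dict[str, Alignment] = {}
    meta_records: list[MetadataRecord] = []
    anchor_intervals: dict[str, list[tuple[int, int]]] = {}
    fragment_lengths: dict[tuple[str, str], tuple[int, ...]] = {}

    for marker in markers:
        anchors = [
            _random_seq(rng, config.conserved_block_length)
            for _ in range(config.conserved_blocks_per_marker)
        ]
        base = rng.integers(lo_b, hi_b + 1, size=n_hv)
        if config.distinct_species_effects:
            effects = np.stack(
                [
                    rng.choice(
                        np.arange(lo_e, hi_e + 1), size=config.n_species, replace=False
                    )
                    for _ in range(n_hv)
                ],
                axis=1,
            )  # (n_species, n_hv)
        else:
            effects = rng.integers(lo_e, hi_e + 1, size=(config.n_species, n_hv))

        lengths_by_acc: dict[str, list[int]] = {}
        segments_by_acc: dict[str, list[str]] = {}
        present: list[str] = []
        for accession, sp in accessions:
            sp_idx = species.index(sp)
            lengths: list[int] = []
            segments: list[str] = []
            for r in range(n_hv):
                length = int(base[r]) + int(effects[sp_idx, r])
                if (
                    config.intraspecific_indel_prob > 0
                    and rng.random() < config.intraspecific_indel_prob
                ):
                    size = int(rng.integers(lo_s, hi_s + 1))
                    sign = 1 if rng.random() < 0.5 else -1
                    length += sign * size
                length = max(0, length)
                lengths.append(length)
                segments.append(_random_seq(rng, length))
            missing = (
                config.missing_prob > 0 and rng.random() < config.missing_prob
            )
            if missing:
                continue
            present.append(accession)
            lengths_by_acc[accession] = lengths
            segments_by_acc[accession] = segments
            fragment_lengths[(accession, marker)] = tuple(lengths)

        if not present:
            raise ConfigError(
                f"missing_prob={config.missing_prob} removed every sequence "
                f"of marker {marker!r}"
            )
        region_widths = [
            max(lengths_by_acc[a][r] for a in present) for r in range(n_hv)
        ]
        # alignment columns: anchor0 | hv0 padded | anchor1 | ... | anchorB-1
        intervals: list[tuple[int, int]] = []
        col = 0
        for b in range(config.conserved_blocks_per_marker):
            intervals.append((col, col + config.conserved_block_length))
            col += config.conserved_block_length
            if b < n_hv:
                col += region_widths[b]
        anchor_intervals[marker] = intervals

        sequences = []
        for accession, sp in accessions:
            if accession not in lengths_by_acc:
                continue
            parts = []
            for b in range(config.conserved_blocks_per_marker):
                parts.append(anchors[b])
                if b < n_hv:
                    seg = segments_by_acc[accession][b]
                    parts.append(seg + "-" * (region_widths[b] - len(seg)))
            seq_id = f"{accession}_{marker}"
            sequences.append((seq_id, "".join(parts)))
            meta_records.append(
                MetadataRecord(
                    sequence_id=seq_id,
                    accession=accession,
                    species=sp,
                    subspecies=None,
                    marker=marker,
                )
            )
        alignments[marker] = Alignment(
            marker_name=marker, sequences=tuple(sequences)
        )

    truth = GroundTruth(
        anchor_intervals=anchor_intervals,
        fragment_lengths=fragment_lengths,
        species_assignment={a: sp for a, sp in accessions},
        markers=markers,
    )
    return SimulationResult(
        alignments=alignments,
        metadata=SampleMetadata(records=meta_records),
        truth=truth,
        config=config,
    )


def truth_profiles(gt: GroundTruth) -> ProfileTable:
    """Profile table built directly from planted lengths (the end-to-end oracle)."""
    panel: list[str] = []
    hv_counts: dict[str, int] = {}
    for marker in gt.markers:
        n_hv = len(gt.anchor_intervals[marker]) - 1
        hv_counts[marker] = n_hv
        panel.extend(f"{marker}:hv{r}" for r in range(n_hv))
    rows: list[ProfileRow] = []
    for accession in sorted(gt.species_assignment):
        lengths: list[Optional[int]] = []
        for marker in gt.markers:
            stored = gt.fragment_lengths.get((accession, marker))
            if stored is None:
                lengths.extend([None] * hv_counts[marker])
            else:
                lengths.extend(stored)
        rows.append(
            ProfileRow(
                accession=accession,
                species=gt.species_assignment[accession],
                lengths=tuple(lengths),
            )
        )
    return ProfileTable(panel=panel, rows=rows)


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-marker FASTA, metadata TSV, true-anchor regions TSV and
    truth profiles TSV; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    regions: list[ConservedRegion] = []
    for marker, aln in result.alignments.items():
        p = outdir / f"{marker}.fasta"
        write_alignment(aln, p)
        paths[f"alignment:{marker}"] = p
        for i, (start, end) in enumerate(result.truth.anchor_intervals[marker]):
            consensus = aln.sequences[0][1][start:end]
            regions.append(
                ConservedRegion(
                    marker_name=marker,
                    region_index=i,
                    start=start,
                    end=end,
                    consensus=consensus,
                )
            )
    meta_path = outdir / "metadata.tsv"
    write_metadata(result.metadata, meta_path)
    paths["metadata"] = meta_path
    regions_path = outdir / "regions.tsv"
    write_regions(regions, regions_path)
    paths["regions"] = regions_path
    truth_path = outdir / "truth_profiles.tsv"
    write_profile_table(truth_profiles(result.truth), truth_path)
    paths["truth_profiles"] = truth_path
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=True)
    paths["config"] = config_path
    return paths
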