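"""Profile statistics: specific/shared profile counts, f_sp, mismatch
distributions, and minimum discriminating region subsets.

Definitions
-----------
* A *distinct profile* is a unique length vector among accessions with
  complete profiles.
* A profile is *species-specific* when every accession carrying it
  belongs to a single species.
* ``f_sp`` (default, accession-weighted): fraction of complete-profile
  accessions whose profile is species-specific. A species-level variant
  (fraction of species whose accessions all carry species-specific
  profiles) is available via ``definition='species'``.
* The mismatch distribution counts, over all unordered accession pairs,
  the number of panel positions at which the two profiles are both
  present and unequal (pairwise-complete comparison); pairs with no
  comparable position are excluded and reported separately.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ParameterError, PanelSizeError, UndefinedStatisticError
from .profiler import ProfileTable

__all__ = [
    "ProfileGroup",
    "PairwiseResult",
    "RegionStats",
    "classify_profiles",
    "species_specific_frequency",
    "pairwise_differences",
    "min_discriminating_subset",
    "region_stats",
    "aggregate_means",
]

MAX_EXHAUSTIVE_POOL = 20


@dataclass(frozen=True)
class ProfileGroup:
    """One distinct profile with the accessions and species carrying it."""

    lengths: tuple[int, ...]
    accessions: tuple[str, ...]
    species: frozenset[str]

    @property
    def species_specific(self) -> bool:
        return len(self.species) == 1


@dataclass
class PairwiseResult:
    """Mismatch distribution over unordered accession pairs."""

    distribution: dict[int, int]
    mean: float
    n_pairs: int
    n_incomparable: int = 0


@dataclass
class RegionStats:
    """The per-region statistics row reported for each marker."""

    n_conserved: int
    n_hypervariable: int
    n_distinct_profiles: int
    n_species_specific_profiles: int
    n_species_shared_profiles: int
    n_species_with_shared_profiles: int
    f_sp: float
    avg_pairwise_differences: float
    avg_pairwise_differences_per_region: float
    min_regions_for_discrimination: Optional[int]
    mismatch_distribution: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_conserved": self.n_conserved,
            "n_hypervariable": self.n_hypervariable,
            "n_distinct_profiles": self.n_distinct_profiles,
            "n_species_specific_profiles": self.n_species_specific_profiles,
            "n_species_shared_profiles": self.n_species_shared_profiles,
            "n_species_with_shared_profiles": self.n_species_with_shared_profiles,
            "f_sp": self.f_sp,
            "avg_pairwise_differences": self.avg_pairwise_differences,
            "avg_pairwise_differences_per_region": (
                self.avg_pairwise_differences_per_region
            ),
            "min_regions_for_discrimination": (
                "not achievable"
                if self.min_regions_for_discrimination is None
                else self.min_regions_for_discrimination
            ),
            "mismatch_distribution": {
                str(k): v for k, v in sorted(self.mismatch_distribution.items())
            },
        }
        return d


def classify_profiles(table: ProfileTable) -> list[ProfileGroup]:
    """Group complete profiles by identical length vectors.

    Groups are returned sorted by length vector for reproducibility.
    """
    if not table.rows:
        raise UndefinedStatisticError("profile table has no rows")
    buckets: dict[tuple[int, ...], list] = {}
    for row in table.complete_rows():
        buckets.setdefault(row.lengths, []).append(row)
    return [
        ProfileGroup(
            lengths=lengths,
            accessions=tuple(sorted(r.accession for r in rows)),
            species=frozenset(r.species for r in rows),
        )
        for lengths, rows in sorted(buckets.items())
    ]


def species_specific_frequency(
    table: ProfileTable, definition: str = "accession"
) -> float:
    """Frequency of species-specific profiles.

    ``definition='accession'`` (default): fraction of complete-profile
    accessions carrying a species-specific profile.
    ``definition='species'``: fraction of species all of whose
    complete-profile accessions carry species-specific profiles.
    """
    if definition not in ("accession", "species"):
        raise ParameterError(f"unknown f_sp definition {definition!r}")
    groups = classify_profiles(table)
    if not groups:
        raise UndefinedStatisticError("no complete profiles; f_sp undefined")
    if definition == "accession":
        total = sum(len(g.accessions) for g in groups)
        specific = sum(len(g.accessions) for g in groups if g.species_specific)
        return specific / total
    specific_species = set()
    unspecific_species = set()
    for g in groups:
        if g.species_specific:
            specific_species.update(g.species)
        else:
            unspecific_species.update(g.species)
    all_species = specific_species | unspecific_species
    return len(all_species - unspecific_species) / len(all_species)


def _pair_difference(a: Sequence[Optional[int]], b: Sequence[Optional[int]]):
    """(difference count, comparable count) under pairwise-complete rules."""
    comparable = 0
    diff = 0
    for x, y in zip(a, b):
        if x is None or y is None:
            continue
        comparable += 1
        if x != y:
            diff += 1
    return diff, comparable


def pairwise_differences(table: ProfileTable) -> PairwiseResult:
    """Mismatch distribution over all unordered accession pairs."""
    if len(table.rows) < 2:
        raise UndefinedStatisticError("need >= 2 rows for pairwise differences")
    dist: Counter[int] = Counter()
    incomparable = 0
    for a, b in itertools.combinations(table.rows, 2):
        diff, comparable = _pair_difference(a.lengths, b.lengths)
        if comparable == 0:
            incomparable += 1
            continue
        dist[diff] += 1
    n_pairs = sum(dist.values())
    mean = (
        sum(k * v for k, v in dist.items()) / n_pairs if n_pairs else float("nan")
    )
    return PairwiseResult(
        distribution=dict(sorted(dist.items())),
        mean=mean,
        n_pairs=n_pairs,
        n_incomparable=incomparable,
    )


def _species_disjoint(table: ProfileTable, subset: Sequence[int]) -> bool:
    """True when no restricted profile is shared across species.

    Missing lengths participate as their own value, so two species
    sharing an all-missing restriction are not discriminated.
    """
    carriers: dict[tuple, str] = {}
    for row in table.rows:
        key = tuple(row.lengths[p] for p in subset)
        known = carriers.get(key)
        if known is None:
            carriers[key] = row.species
        elif known != row.species:
            return False
    return True


def min_discriminating_subset(
    table: ProfileTable, pool: Optional[Sequence[int]] = None
):
    """Smallest region subset whose restricted profiles separate all species.

    Exhaustively searches subsets of ``pool`` (default: all panel
    positions) in increasing cardinality. Returns ``(k, witnesses)``
    with every witness subset of minimum size ``k`` in lexicographic
    order, or ``(None, [])`` when even the full pool fails.
    """
    positions = list(range(len(table.panel))) if pool is None else sorted(set(pool))
    if not positions:
        raise ParameterError("pool must be nonempty")
    for p in positions:
        if not (0 <= p < len(table.panel)):
            raise ParameterError(f"pool position {p} out of range")
    if len(positions) > MAX_EXHAUSTIVE_POOL:
        raise PanelSizeError(
            f"pool of {len(positions)} regions exceeds exhaustive-search limit "
            f"({MAX_EXHAUSTIVE_POOL}); restrict the pool"
        )
    if not _species_disjoint(table, positions):
        return None, []
    for k in range(1, len(positions) + 1):
        witnesses = [
            tuple(sub)
            for sub in itertools.combinations(positions, k)
            if _species_disjoint(table, sub)
        ]
        if witnesses:
            return k, witnesses
    return None, []  # pragma: no cover - unreachable: full pool checked above


def region_stats(
    table: ProfileTable,
    conserved_count: int = 0,
    fsp_definition: str = "accession",
    pool: Optional[Sequence[int]] = None,
) -> RegionStats:
    """Assemble the full statistics row for one marker (or merged panel)."""
    groups = classify_profiles(table)
    if not groups:
        raise UndefinedStatisticError("no complete profiles")
    n_distinct = len(groups)
    n_specific = sum(1 for g in groups if g.species_specific)
    shared_groups = [g for g in groups if not g.species_specific]
    species_with_shared = set()
    for g in shared_groups:
        species_with_shared.update(g.species)
    pw = pairwise_differences(table)
    n = len(table.panel)
    min_k, _ = min_discriminating_subset(table, pool=pool)
    return RegionStats(
        n_conserved=conserved_count,
        n_hypervariable=n,
        n_distinct_profiles=n_distinct,
        n_species_specific_profiles=n_specific,
        n_species_shared_profiles=n_distinct - n_specific,
        n_species_with_shared_profiles=len(species_with_shared),
        f_sp=species_specific_frequency(table, definition=fsp_definition),
        avg_pairwise_differences=pw.mean,
        avg_pairwise_differences_per_region=pw.mean / n,
        min_regions_for_discrimination=min_k,
        mismatch_distribution=pw.distribution,
    )


def aggregate_means(values: Iterable[float], ndigits: int = 2) -> float:
    """Arithmetic mean of per-region statistics, rounded for reporting."""
    values = list(values)
    if not values:
        raise UndefinedStatisticError("cannot aggregate an empty value list")
    return round(sum(values) / len(values), ndigits)
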