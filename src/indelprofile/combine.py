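"""Concatenated multi-marker analysis: combination enumeration, the
concatenated mismatch distribution, and region-pair discriminatory
potential matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import ParameterError, PanelSizeError
from .profiler import ProfileTable, marker_of_label
from .regions import PERIPHERAL_SUFFIX
from .stats import PairwiseResult, pairwise_differences, species_specific_frequency

__all__ = [
    "CombinationResult",
    "RegionPairMatrix",
    "drop_peripheral",
    "enumerate_combinations",
    "greedy_max_fsp",
    "concatenated_mismatch",
    "region_pair_matrix",
]

MAX_ENUM_PANEL = 20


@dataclass(frozen=True)
class CombinationResult:
    """Statistics of one region-subset of the panel."""

    subset: tuple[int, ...]
    labels: tuple[str, ...]
    f_sp: float
    n_distinct_profiles: int
    avg_pairwise_differences: float
    approximate: bool = False

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "labels": list(self.labels),
            "f_sp": self.f_sp,
            "n_distinct_profiles": self.n_distinct_profiles,
            "avg_pairwise_differences": self.avg_pairwise_differences,
            "approximate": self.approximate,
        }


@dataclass
class RegionPairMatrix:
    """Symmetric matrix of average per-region pairwise differences.

    Cell (i, j) is the mean pairwise difference count over the union of
    the two groups' regions divided by the union size; the diagonal
    carries the individual (single-group) values.
    """

    labels: list[str]
    values: list[list[float]]

    def to_dict(self) -> dict:
        return {"labels": self.labels, "values": self.values}


def drop_peripheral(table: ProfileTable) -> ProfileTable:
    """Remove peripheral hypervariable regions (labels marked at profiling)."""
    keep = [
        i for i, lab in enumerate(table.panel) if not lab.endswith(PERIPHERAL_SUFFIX)
    ]
    if not keep:
        raise ParameterError("all panel regions are peripheral; nothing to analyse")
    return table.restrict(keep)


def _combo(table: ProfileTable, subset: tuple[int, ...], approximate=False):
    sub = table.restrict(subset)
    distinct = {r.lengths for r in sub.complete_rows()}
    pw = pairwise_differences(sub)
    return CombinationResult(
        subset=subset,
        labels=tuple(sub.panel),
        f_sp=species_specific_frequency(sub),
        n_distinct_profiles=len(distinct),
        avg_pairwise_differences=pw.mean,
        approximate=approximate,
    )


def enumerate_combinations(table: ProfileTable) -> list[CombinationResult]:
    """All 2^n - 1 nonempty region subsets with their statistics.

    Sorted by f_sp descending, then subset size ascending, then
    lexicographically — the head of the list is the best combination.
    """
    n = len(table.panel)
    if n == 0:
        raise ParameterError("empty panel")
    if n > MAX_ENUM_PANEL:
        raise PanelSizeError(
            f"panel of {n} regions exceeds enumeration limit ({MAX_ENUM_PANEL}); "
            "restrict the pool or use greedy_max_fsp"
        )
    results = [
        _combo(table, subset)
        for k in range(1, n + 1)
        for subset in itertools.combinations(range(n), k)
    ]
    results.sort(key=lambda r: (-r.f_sp, len(r.subset), r.subset))
    return results


def greedy_max_fsp(table: ProfileTable) -> CombinationResult:
    """Greedy forward selection of a high-f_sp subset (approximate).

    Fallback for panels too large for exhaustive enumeration.
    """
    n = len(table.panel)
    if n == 0:
        raise ParameterError("empty panel")
    chosen: list[int] = []
    best = -1.0
    remaining = set(range(n))
    while remaining:
        scored = [
            (species_specific_frequency(table.restrict(sorted(chosen + [p]))), p)
            for p in sorted(remaining)
        ]
        gain, pick = max(scored)
        if gain <= best:
            break
        best = gain
        chosen.append(pick)
        remaining.discard(pick)
    return _combo(table, tuple(sorted(chosen)), approximate=True)


def concatenated_mismatch(table: ProfileTable) -> PairwiseResult:
    """Mismatch distribution of the concatenated panel (alias with intent)."""
    return pairwise_differences(table)


def region_pair_matrix(table: ProfileTable, by_marker: bool = True) -> RegionPairMatrix:
    """Pairwise discriminatory-potential matrix.

    With ``by_marker`` panel positions are grouped by their marker
    prefix; otherwise every region is its own group.
    """
    if by_marker:
        groups: dict[str, list[int]] = {}
        order: list[str] = []
        for i, lab in enumerate(table.panel):
            m = marker_of_label(lab)
            if m not in groups:
                groups[m] = []
                order.append(m)
            groups[m].append(i)
        labels = order
        members = [groups[m] for m in order]
    else:
        labels = list(table.panel)
        members = [[i] for i in range(len(table.panel))]
    if len(members) < 2:
        raise ParameterError("need >= 2 regions/markers for a pair matrix")
    k = len(members)
    values = [[0.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i, k):
            union = sorted(set(members[i]) | set(members[j]))
            pw = pairwise_differences(table.restrict(union))
            cell = pw.mean / len(union)
            values[i][j] = cell
            values[j][i] = cell
    return RegionPairMatrix(labels=labels, values=values)
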