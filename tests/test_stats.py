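import itertools

import numpy as np
import pytest

from indelprofile.errors import (
    PanelSizeError,
    ParameterError,
    UndefinedStatisticError,
)
from indelprofile.stats import (
    aggregate_means,
    classify_profiles,
    min_discriminating_subset,
    pairwise_differences,
    region_stats,
    species_specific_frequency,
)

from conftest import make_table, random_table


# ---------------------------------------------------------------- oracles

def oracle_min_subset(table, pool):
    """Independent full-enumeration oracle for the minimum region subset."""
    for k in range(1, len(pool) + 1):
        hits = []
        for sub in itertools.combinations(sorted(pool), k):
            seen = {}
            ok = True
            for row in table.rows:
                key = tuple(row.lengths[p] for p in sub)
                if seen.setdefault(key, row.species) != row.species:
                    ok = False
                    break
            if ok:
                hits.append(sub)
        if hits:
            return k, hits
    return None, []


class TestClassifyProfiles:
    def test_all_distinct(self):
        t = make_table(
            ["m:hv0"],
            [("a1", "spA", (1,)), ("a2", "spB", (2,)), ("a3", "spC", (3,))],
        )
        groups = classify_profiles(t)
        assert len(groups) == 3
        assert all(g.species_specific for g in groups)

    def test_two_species_share_one_profile(self):
        t = make_table(["m:hv0"], [("a1", "spA", (1,)), ("a2", "spB", (1,))])
        groups = classify_profiles(t)
        assert len(groups) == 1
        assert not groups[0].species_specific
        assert groups[0].species == {"spA", "spB"}

    def test_within_species_sharing_is_still_specific(self):
        t = make_table(["m:hv0"], [("a1", "spA", (1,)), ("a2", "spA", (1,))])
        groups = classify_profiles(t)
        assert len(groups) == 1
        assert groups[0].species_specific

    def test_identity_nsp_plus_shared_equals_n(self, rng):
        for _ in range(50):
            t = random_table(rng)
            groups = classify_profiles(t)
            n = len(groups)
            nsp = sum(1 for g in groups if g.species_specific)
            shared = sum(1 for g in groups if not g.species_specific)
            assert nsp + shared == n


class TestSpeciesSpecificFrequency:
    def test_all_unique_gives_one(self):
        t = make_table(
            ["m:hv0"], [(f"a{i}", f"sp{i}", (i,)) for i in range(5)]
        )
        assert species_specific_frequency(t) == 1.0

    def test_two_species_sharing_one_profile(self):
        t = make_table(
            ["m:hv0"],
            [("a1", "spA", (1,)), ("a2", "spB", (1,)), ("a3", "spC", (2,))],
        )
        assert species_specific_frequency(t) == pytest.approx(1 / 3)

    def test_32_of_35_specific(self):
        # 32 accessions with unique profiles, 3 accessions of 3 species
        # sharing one profile -> f_sp = 32/35 ~ 0.91
        rows = [(f"a{i:02d}", f"sp{i:02d}", (100 + i,)) for i in range(32)]
        rows += [(f"b{i}", f"shared{i}", (999,)) for i in range(3)]
        t = make_table(["m:hv0"], rows)
        assert species_specific_frequency(t) == pytest.approx(32 / 35)
        assert round(species_specific_frequency(t), 2) == 0.91

    def test_species_level_definition(self):
        # spA has one shared + one unique accession: not fully specific
        t = make_table(
            ["m:hv0"],
            [
                ("a1", "spA", (1,)),
                ("a2", "spA", (5,)),
                ("a3", "spB", (1,)),
                ("a4", "spC", (7,)),
            ],
        )
        assert species_specific_frequency(t, definition="species") == pytest.approx(
            1 / 3
        )

    def test_unknown_definition(self, simple_table):
        with pytest.raises(ParameterError):
            species_specific_frequency(simple_table, definition="bogus")

    def test_all_incomplete_undefined(self):
        t = make_table(["m:hv0"], [("a1", "spA", (None,)), ("a2", "spB", (None,))])
        with pytest.raises(UndefinedStatisticError):
            species_specific_frequency(t)

    def test_invariant_under_row_and_panel_permutation(self, rng):
        for _ in range(20):
            t = random_table(rng, n_regions=3)
            base = species_specific_frequency(t)
            perm_rows = make_table(
                t.panel,
                [
                    (r.accession, r.species, r.lengths)
                    for r in reversed(t.rows)
                ],
            )
            perm = rng.permutation(3)
            perm_panel = t.restrict(list(perm))
            assert species_specific_frequency(perm_rows) == pytest.approx(base)
            assert species_specific_frequency(perm_panel) == pytest.approx(base)

    def test_monotone_under_panel_growth(self, rng):
        for _ in range(30):
            t = random_table(rng, n_regions=4)
            sub = t.restrict([0, 1])
            sup = t.restrict([0, 1, 2, 3])
            assert species_specific_frequency(sup) >= species_specific_frequency(sub)


class TestPairwiseDifferences:
    def test_pair_count_identity(self):
        t = make_table(
            ["m:hv0"], [(f"a{i:02d}", "spA", (i,)) for i in range(35)]
        )
        pw = pairwise_differences(t)
        assert pw.n_pairs == 595
        assert sum(pw.distribution.values()) == 595

    def test_identical_rows(self):
        t = make_table(["m:hv0"], [(f"a{i}", "spA", (7,)) for i in range(6)])
        pw = pairwise_differences(t)
        assert pw.distribution == {0: 15}
        assert pw.mean == 0.0

    def test_hand_enumerated_example(self):
        # (1,1) vs (1,2) -> 1; (1,1) vs (2,2) -> 2; (1,2) vs (2,2) -> 1
        t = make_table(
            ["m:hv0", "m:hv1"],
            [("a1", "spA", (1, 1)), ("a2", "spB", (1, 2)), ("a3", "spC", (2, 2))],
        )
        pw = pairwise_differences(t)
        assert pw.distribution == {1: 2, 2: 1}
        assert pw.mean == pytest.approx(4 / 3)

    def test_mean_identity(self, rng):
        for _ in range(20):
            t = random_table(rng, missing_prob=0.2)
            if len(t.rows) < 2:
                continue
            pw = pairwise_differences(t)
            if pw.n_pairs == 0:
                continue
            expect = sum(k * v for k, v in pw.distribution.items()) / pw.n_pairs
            assert pw.mean == pytest.approx(expect)
            assert 0 <= pw.mean <= len(t.panel)

    def test_missing_positions_skipped(self):
        t = make_table(
            ["m:hv0", "m:hv1"],
            [("a1", "spA", (1, None)), ("a2", "spB", (2, 5))],
        )
        pw = pairwise_differences(t)
        assert pw.distribution == {1: 1}

    def test_fully_incomparable_pair_reported(self):
        t = make_table(
            ["m:hv0"],
            [("a1", "spA", (None,)), ("a2", "spB", (1,))],
        )
        pw = pairwise_differences(t)
        assert pw.n_incomparable == 1
        assert pw.n_pairs == 0

    def test_needs_two_rows(self):
        t = make_table(["m:hv0"], [("a1", "spA", (1,))])
        with pytest.raises(UndefinedStatisticError):
            pairwise_differences(t)


class TestMinDiscriminatingSubset:
    def test_needs_two_regions(self):
        t = make_table(
            ["A", "B"],
            [
                ("a1", "sp1", (1, 3)),
                ("a2", "sp2", (1, 4)),
                ("a3", "sp3", (2, 4)),
            ],
        )
        k, witnesses = min_discriminating_subset(t)
        assert k == 2
        assert witnesses == [(0, 1)]

    def test_single_region_suffices(self):
        t = make_table(
            ["A", "B"],
            [("a1", "sp1", (1, 9)), ("a2", "sp2", (2, 9)), ("a3", "sp3", (3, 9))],
        )
        k, witnesses = min_discriminating_subset(t)
        assert k == 1
        assert witnesses == [(0,)]

    def test_not_achievable(self):
        t = make_table(
            ["A"], [("a1", "sp1", (1,)), ("a2", "sp2", (1,))]
        )
        k, witnesses = min_discriminating_subset(t)
        assert k is None and witnesses == []

    def test_within_species_variation_allowed(self):
        # two accessions of sp1 differ from each other but not across species
        t = make_table(
            ["A"],
            [("a1", "sp1", (1,)), ("a2", "sp1", (2,)), ("a3", "sp2", (3,))],
        )
        k, _ = min_discriminating_subset(t)
        assert k == 1

    def test_empty_pool_rejected(self, simple_table):
        with pytest.raises(ParameterError):
            min_discriminating_subset(simple_table, pool=[])

    def test_pool_guard(self):
        t = make_table(
            [f"r{i}" for i in range(21)],
            [("a1", "sp1", tuple(range(21)))],
        )
        with pytest.raises(PanelSizeError):
            min_discriminating_subset(t)

    def test_matches_oracle_on_random_panels(self, rng):
        for _ in range(60):
            t = random_table(rng, n_regions=int(rng.integers(1, 7)), max_len=2)
            pool = list(range(len(t.panel)))
            got = min_discriminating_subset(t, pool=pool)
            want = oracle_min_subset(t, pool)
            assert got[0] == want[0]
            assert sorted(got[1]) == sorted(want[1])

    def test_monotone_in_pool(self, rng):
        for _ in range(30):
            t = random_table(rng, n_regions=5, max_len=3)
            k_small, _ = min_discriminating_subset(t, pool=[0, 1, 2])
            k_big, _ = min_discriminating_subset(t, pool=[0, 1, 2, 3, 4])
            if k_small is not None:
                assert k_big is not None and k_big <= k_small


class TestRegionStats:
    def test_structural_row(self, simple_table):
        rs = region_stats(simple_table, conserved_count=3)
        assert rs.n_conserved == 3
        assert rs.n_hypervariable == 2
        assert rs.n_distinct_profiles == 3
        assert rs.n_species_specific_profiles == 3
        assert rs.n_species_shared_profiles == 0
        assert rs.f_sp == 1.0
        assert rs.min_regions_for_discrimination == 2
        assert sum(rs.mismatch_distribution.values()) == 3
        assert rs.avg_pairwise_differences_per_region == pytest.approx(
            rs.avg_pairwise_differences / 2
        )

    def test_shared_profile_bookkeeping(self):
        t = make_table(
            ["m:hv0"],
            [("a1", "spA", (1,)), ("a2", "spB", (1,)), ("a3", "spC", (2,))],
        )
        rs = region_stats(t)
        assert rs.n_distinct_profiles == 2
        assert rs.n_species_specific_profiles == 1
        assert rs.n_species_shared_profiles == 1
        assert rs.n_species_with_shared_profiles == 2
        assert rs.min_regions_for_discrimination is None
        assert rs.to_dict()["min_regions_for_discrimination"] == "not achievable"


class TestAggregateMeans:
    def test_mean_nsp_four_markers(self):
        assert aggregate_means([1, 2, 4, 3]) == 2.5

    def test_mean_fsp_six_markers(self):
        assert aggregate_means([0.89, 0.72, 0.45, 0.67, 0.81, 0.86]) == 0.73

    def test_empty_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            aggregate_means([])
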