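import numpy as np
import pytest

from indelprofile.profiler import ProfileRow, ProfileTable


def make_table(panel, rows):
    """Build a ProfileTable from (accession, species, lengths) triples."""
    return ProfileTable(
        panel=list(panel),
        rows=[
            ProfileRow(accession=a, species=s, lengths=tuple(lengths))
            for a, s, lengths in rows
        ],
    )


def random_table(rng: np.random.Generator, n_regions=None, n_rows=None, max_len=4,
                 missing_prob=0.0, n_species=None):
    """A random profile table for property tests."""
    n_regions = n_regions or int(rng.integers(1, 6))
    n_rows = n_rows or int(rng.integers(2, 9))
    n_species = n_species or int(rng.integers(1, min(n_rows, 4) + 1))
    rows = []
    for i in range(n_rows):
        lengths = tuple(
            None if rng.random() < missing_prob else int(rng.integers(0, max_len + 1))
            for _ in range(n_regions)
        )
        rows.append(
            (f"acc{i:03d}", f"sp{int(rng.integers(0, n_species)):02d}", lengths)
        )
    return make_table([f"m:hv{j}" for j in range(n_regions)], rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def simple_table():
    # three single-accession species, profiles engineered so that no single
    # region separates all three but the pair {0, 1} does
    return make_table(
        ["m:hv0", "m:hv1"],
        [
            ("acc1", "spA", (1, 3)),
            ("acc2", "spB", (1, 4)),
            ("acc3", "spC", (2, 4)),
        ],
    )
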