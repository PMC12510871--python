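import numpy as np
import pandas as pd
import pytest

from coral.data import CommunityData, TaxonomyTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_taxonomy():
    """Four species: sp1/sp2 same genus, sp3 same order, sp4 shares only kingdom."""
    rows = {
        "sp1": ["k1", "p1", "c1", "o1", "f1", "sf1", "t1", "g1", "s1"],
        "sp2": ["k1", "p1", "c1", "o1", "f1", "sf1", "t1", "g1", "s2"],
        "sp3": ["k1", "p1", "c1", "o1", "f2", "sf2", "t2", "g2", "s3"],
        "sp4": ["k1", "p2", "c9", "o9", "f9", "sf9", "t9", "g9", "s4"],
    }
    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=[
            "kingdom", "phylum", "class", "order", "family",
            "subfamily", "tribe", "genus", "species",
        ],
    )
    table.index.name = "species_id"
    return TaxonomyTable(table)


@pytest.fixture
def toy_community():
    Y = pd.DataFrame(
        [[1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 0]],
        index=pd.Index(["a", "b", "c"], name="sample_id"),
        columns=["sp1", "sp2", "sp3", "sp4"],
    )
    cov = pd.DataFrame(
        {
            "site": ["s1", "s1", "s2"],
            "day": [0.0, 91.25, 200.0],
            "temperature": [20.0, 22.0, 18.0],
            "precipitation": [800.0, 950.0, 700.0],
            "seq_depth": [10000, 20000, 15000],
        },
        index=pd.Index(["a", "b", "c"], name="sample_id"),
    )
    return CommunityData(Y, cov)


def random_taxonomy(rng, n_species, n_groups_per_level=3):
    """Random (not necessarily nested) label table — still a valid taxonomy."""
    from coral.data import DEFAULT_RANKS

    labels = {}
    for lvl, rank in enumerate(DEFAULT_RANKS):
        n_groups = 1 if lvl == 0 else min(n_species, n_groups_per_level * lvl)
        labels[rank] = [f"{rank}_{rng.integers(n_groups)}" for _ in range(n_species)]
    table = pd.DataFrame(labels, index=pd.Index([f"sp{j}" for j in range(n_species)]))
    return TaxonomyTable(table)
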