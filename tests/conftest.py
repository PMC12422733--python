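import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import teconet as tc


@pytest.fixture(scope="session")
def planted_data():
    """Two-species dataset with six strong planted gene-TE links."""
    links = tuple(
        tc.PlantedLink(
            f"ZNF{i + 1:04d}",
            f"TE{i + 1:04d}",
            0.9,
            sign=(1 if i % 2 == 0 else -1),
        )
        for i in range(6)
    )
    spec = tc.SimSpec(
        n_genes=40,
        n_tes=30,
        n_krabznf=12,
        planted_links=links,
        species=(
            tc.SpeciesSpec("human", 1.0, 4),
            tc.SpeciesSpec("chimp", 1.5, 3),
        ),
        groups=("cortex",),
        samples_per_group=8,
        seed=3,
    )
    return tc.simulate(spec)


@pytest.fixture(scope="session")
def planted_human_expr(planted_data):
    return tc.log_normalize(planted_data.matrices["human"])


@pytest.fixture(scope="session")
def null_data():
    """Independent-feature null dataset (no planted links, no shared
    latent factors): 50 genes x 50 TEs x 24 samples."""
    spec = tc.SimSpec(
        n_genes=50,
        n_tes=50,
        n_krabznf=20,
        species=(tc.SpeciesSpec("human", 1.0, 4),),
        groups=("cortex",),
        samples_per_group=6,
        seed=17,
    )
    return tc.simulate(spec)


@pytest.fixture(scope="session")
def null_expr(null_data):
    return tc.log_normalize(null_data.matrices["human"])


def feature_sets(annotation):
    genes = sorted(annotation.index[annotation["kind"] == "gene"])
    tes = sorted(annotation.index[annotation["kind"] == "TE"])
    return genes, tes


@pytest.fixture(scope="session")
def tiny_matrix():
    """3 features x 4 samples, two groups of two."""
    counts = pd.DataFrame(
        [[10, 12, 40, 44], [5, 6, 5, 7], [100, 90, 110, 95]],
        index=["f1", "f2", "f3"],
        columns=["a1", "a2", "b1", "b2"],
    )
    meta = pd.DataFrame(
        {
            "species": ["human"] * 4,
            "individual": ["i1", "i2", "i3", "i4"],
            "group": ["cortex"] * 4,
            "condition": ["control", "control", "case", "case"],
        },
        index=counts.columns,
    )
    return tc.CountMatrix(counts, meta)
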