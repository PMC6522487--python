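import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import phylosym as ps


@pytest.fixture
def balanced_tree():
    """4-tip balanced tree with known branch lengths."""
    return TreeNode.read(["((a:1.0,b:2.0)ab:0.5,(c:1.0,d:1.0)cd:1.5)root;"])


@pytest.fixture
def toy_table():
    df = pd.DataFrame(
        [[5, 3, 0, 0],
         [0, 2, 4, 0],
         [1, 1, 1, 1],
         [0, 0, 0, 8]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c", "d"],
    )
    return ps.OtuTable(df)


def make_metadata(samples, species, diets=None, lats=None, lons=None,
                  **extra_cols):
    n = len(samples)
    diets = diets or ["herbivore"] * n
    df = pd.DataFrame({
        "host_species": species,
        "class": ["c1"] * n,
        "order": ["o1"] * n,
        "family": ["f1"] * n,
        "genus": ["g1"] * n,
        "species": species,
        "diet_general": diets,
        "latitude": lats if lats is not None else [0.0] * n,
        "longitude": lons if lons is not None else [0.0] * n,
        "sample_type": ["feces"] * n,
        "captivity": ["wild"] * n,
        "diet__grass": [1] * n,
        "hab__forest": [0] * n,
    }, index=pd.Index(samples, name="sample"))
    for k, v in extra_cols.items():
        df[k] = v
    return ps.SampleMetadata(df)


@pytest.fixture
def small_synthetic():
    cfg = ps.SimulationConfig(
        n_species=16, extra_sample_mean=0.7, max_samples_per_species=4,
        n_heritable=4, n_diet_guild=3, n_cospeciating=8, n_consortium=6,
        n_noise=40, noise_p_range=(0.02, 0.2), depth=300, seed=42)
    return ps.simulate_dataset(cfg)
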