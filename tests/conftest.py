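import warnings

import numpy as np
import pytest

from benthoscale.dataio import CommunityMatrix, StationTable
from benthoscale.synthetic import SyntheticConfig, generate_site
import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_site():
    """A small deterministic synthetic site used across modules."""
    cfg = SyntheticConfig(seed=42, n_stations=40, n_provinces=4,
                          n_species=12, domain_km=(3.0, 2.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        community, stations, truth = generate_site(cfg)
    return community, stations, truth


@pytest.fixture
def random_community(rng):
    """An unstructured random community of 8 samples x 5 species."""
    counts = rng.integers(1, 40, size=(8, 5)).astype(float)
    return CommunityMatrix(sample_ids=[f"S{i}" for i in range(8)],
                           species_ids=[f"sp{j}" for j in range(5)],
                           counts=counts)


@pytest.fixture
def random_stations(rng):
    coords = rng.uniform(0, 3.0, size=(8, 2))
    ids = [f"S{i}" for i in range(8)]
    return StationTable(sample_ids=ids, x_km=coords[:, 0], y_km=coords[:, 1],
                        province=pd.Series(["A"] * 4 + ["B"] * 4, index=ids),
                        environment=pd.DataFrame(index=ids))
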