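import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import erdiv

settings.register_profile(
    "erdiv",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("erdiv")


@pytest.fixture(scope="session")
def table1():
    return erdiv.fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return erdiv.fixture("table2")


@pytest.fixture(scope="session")
def table3():
    """(abundance, metadata) for the ten-biome example."""
    return erdiv.fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return erdiv.fixture("table4")


@pytest.fixture(scope="session")
def er3(table3):
    """ER coordinate table of the ten-biome example."""
    return erdiv.er_table(table3[0])


@pytest.fixture(scope="session")
def dist3(er3):
    """Euclidean (richness, NME) distance matrix of the ten-biome example."""
    return erdiv.er_distances(er3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_er_dataset(rng, n_per_group=4, n_groups=2):
    """Random ER-style coordinates + one-factor metadata for property tests."""
    n = n_per_group * n_groups
    coords = pd.DataFrame(
        {
            "richness": rng.integers(2, 12, size=n).astype(float),
            "nme": rng.uniform(0.1, 1.0, size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    metadata = pd.DataFrame(
        {"Group": np.repeat([f"g{j}" for j in range(n_groups)], n_per_group)},
        index=coords.index,
    )
    return coords, metadata
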