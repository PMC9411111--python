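import numpy as np
import pandas as pd
import pytest

from ecostate import StateVariables

# triples spanning the regimes N/S in [3, 1000], E/N in [5, 1000]
TRIPLES = [
    StateVariables(10, 30, 300),
    StateVariables(10, 1000, 25000),
    StateVariables(16, 64, 640),
    StateVariables(30, 3000, 1e5),
    StateVariables(50, 5000, 5e6),
    StateVariables(100, 1e5, 1e6),
]


@pytest.fixture(scope="session")
def triples():
    return list(TRIPLES)


@pytest.fixture
def rng():
    return np.random.default_rng(20220825)


def make_mass_census(masses, n_species=None, plot_label="test"):
    """A CommunityCensus over the given masses, species assigned round-robin."""
    from ecostate import CommunityCensus

    masses = np.asarray(masses, dtype=float)
    k = n_species or min(3, len(masses))
    species = [f"sp{i % k}" for i in range(len(masses))]
    return CommunityCensus(
        table=pd.DataFrame({"species": species, "measurement": masses}),
        measurement_kind="mass", plot_label=plot_label)
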