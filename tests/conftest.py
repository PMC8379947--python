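import numpy as np
import pandas as pd
import pytest

from xylemsem.simulate import SimConfig, simulate_from_sem, simulate_replicates
from xylemsem.xylem_models import TRAIT_NAMES


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=20260921)


@pytest.fixture(scope="session")
def species_table(sim_config):
    """A 29-species synthetic table on the transformed scale."""
    return simulate_from_sem(sim_config)


@pytest.fixture(scope="session")
def replicate_table(sim_config, species_table):
    return simulate_replicates(species_table, sim_config)


@pytest.fixture()
def raw_species_csv(tmp_path):
    """A small raw-scale species CSV (negative water potentials,
    proportions in [0, 1]) for the loading/transform path."""
    rng = np.random.default_rng(42)
    n = 8
    fiber = rng.uniform(0.4, 0.7, n)
    vessel = rng.uniform(0.05, 0.2, n)
    parenchyma = np.clip(1.0 - fiber - vessel, 0.05, 0.5)
    df = pd.DataFrame({
        "species": [f"sp{i}" for i in range(n)],
        "site": ["A", "B"] * (n // 2),
        "pmin": -rng.uniform(2, 9, n),
        "p75": -rng.uniform(3, 11, n),
        "ks": rng.uniform(0.5, 4.0, n),
        "capacitance": rng.uniform(0.03, 0.15, n),
        "starch": rng.uniform(1.0, 6.0, n),
        "density": rng.uniform(0.4, 0.75, n),
        "fiber": fiber,
        "vessel": vessel,
        "parenchyma": parenchyma,
    })
    assert list(df.columns[2:]) == list(TRAIT_NAMES)
    path = tmp_path / "species.csv"
    df.to_csv(path, index=False)
    return path, df
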