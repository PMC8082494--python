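import numpy as np
import pandas as pd
import pytest

from ligandshift.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_proteins=200,
        n_de_proteins=10,
        peptides_per_condition=300,
        n_variants=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_observations(rows) -> pd.DataFrame:
    """Observation table from (sequence, protein, start, end, condition,
    bio_rep, tech_rep, ms1_area, mhc_class) tuples."""
    return pd.DataFrame(rows, columns=[
        "sequence", "protein", "start", "end", "condition", "bio_rep",
        "tech_rep", "ms1_area", "mhc_class",
    ])
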