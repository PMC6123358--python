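import numpy as np
import pandas as pd
import pytest

from culturomics import OtuTable, SimulationParams, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_table():
    """Hand-built 3-sample x 4-OTU count table."""
    return OtuTable(
        pd.DataFrame(
            [[3, 0, 1, 2], [0, 2, 0, 7], [1, 1, 1, 0]],
            index=["s1", "s2", "s3"],
            columns=["o1", "o2", "o3", "o4"],
        )
    )


def random_table(rng, n_samples=20, n_otus=50, lam=2.0):
    return OtuTable(
        pd.DataFrame(
            rng.poisson(lam, size=(n_samples, n_otus)),
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"o{j}" for j in range(n_otus)],
        )
    )


@pytest.fixture
def small_params():
    """Desk-scale simulation for fast pipeline-level tests."""
    return SimulationParams(
        n_taxa=200,
        inoculum_cells=1e5,
        read_depth=1500,
        n_cohort_samples=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_experiment(
        SimulationParams(
            n_taxa=200,
            inoculum_cells=1e5,
            read_depth=1500,
            n_cohort_samples=8,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One experiment at the default study conditions (3000 taxa, 69 samples)."""
    return simulate_experiment(SimulationParams(seed=42))
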