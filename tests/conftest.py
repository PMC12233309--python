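import numpy as np
import pandas as pd
import pytest

from survqtl import (
    PlantedEqtl,
    PlantedSurvival,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully featured twin-cohort world used across tests."""
    return SimulationConfig(
        seed=100,
        n_samples=60,
        n_genes=30,
        n_variants=240,
        planted_eqtls=[
            PlantedEqtl("G0000", 1.5, "shared"),
            PlantedEqtl("G0001", -1.5, "shared"),
        ],
        planted_survival=[
            PlantedSurvival("G0000", 1.0, "shared"),
            PlantedSurvival("G0001", 1.0, "shared"),
        ],
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    bundle, truth = simulate_cohort(small_cfg)
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_clinical():
    """12-sample clinical table with events and censoring."""
    rng = np.random.default_rng(7)
    n = 12
    df = pd.DataFrame(
        {
            "sex": ["male", "female"] * (n // 2),
            "age_group": [0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1],
            "T": rng.integers(1, 5, n),
            "N": rng.integers(0, 3, n),
            "M": rng.integers(0, 2, n),
            "time": rng.uniform(30, 2000, n).round(),
            "event": [1, 1, 0, 1, 0, 1, 1, 0, 1, 1, 0, 1],
        },
        index=pd.Index([f"S{i:02d}" for i in range(n)], name="sample_id"),
    )
    from survqtl import ClinicalTable

    return ClinicalTable(df)
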