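import numpy as np
import pytest

from glucotab import (
    ClinicalTable,
    SimulationConfig,
    canonical_schema,
    simulate_table,
    simulate_worked_fixture,
)


@pytest.fixture(scope="session")
def schema():
    return canonical_schema()


@pytest.fixture(scope="session")
def fixture_table():
    return simulate_worked_fixture()


@pytest.fixture(scope="session")
def clustered_sim():
    """Three well-separated clusters, panel missingness, fixed seed."""
    return simulate_table(SimulationConfig(
        n_patients=600, n_clusters=3, cluster_sep=5.0, seed=1,
    ))


def make_complete_table(schema, n=40, seed=0, target=True):
    """Fully observed table with positive columns (for augmentation tests)."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(10.0, 60.0, size=(n, schema.n_attributes))
    values[:, schema.index_of("A2")] = rng.integers(0, 2, n)
    return ClinicalTable(
        schema=schema,
        values=values,
        observed=np.ones_like(values, dtype=bool),
        target=rng.normal(5.0, 1.0, n) if target else None,
    )


@pytest.fixture()
def complete_table(schema):
    return make_complete_table(schema)
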