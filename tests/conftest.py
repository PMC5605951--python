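import numpy as np
import pandas as pd
import pytest

import cohortsynth as cs
from cohortsynth.schema import ClinicWave, ColumnSpec, CohortSchema

#: fixed seed for the synthetic-cohort draw shared across tests
SIM_SEED = 42


@pytest.fixture(scope="session")
def schema():
    return cs.load_schema("bundled")


@pytest.fixture(scope="session")
def fixture_config():
    return cs.FixtureConfig()  # study defaults: n=15445, seed=2017


@pytest.fixture(scope="session")
def source_table(schema, fixture_config):
    """Default emulated source cohort, with missingness applied."""
    full = cs.generate_source_cohort(fixture_config, schema)
    return cs.apply_missingness(full, fixture_config, schema)


@pytest.fixture(scope="session")
def clean_source(source_table, schema):
    return cs.complete_cases(source_table, schema)


@pytest.fixture(scope="session")
def params(clean_source, schema):
    return cs.estimate_params(clean_source, schema)


@pytest.fixture(scope="session")
def synthetic_155k(params, schema):
    return cs.simulate_dataset(params, schema, 155_000, seed=SIM_SEED)


@pytest.fixture()
def mini_schema():
    """Four-column toy schema: sex + two measurements + age at one clinic."""
    return CohortSchema(
        name="mini",
        waves=[ClinicWave("W1", 7)],
        columns=[
            ColumnSpec("sex", "sex", "sex", None),
            ColumnSpec("height.a", "h", "height", "W1"),
            ColumnSpec("weight.a", "w", "weight", "W1"),
            ColumnSpec("age.a", "a", "age", "W1"),
        ],
    )


def mini_table(n, seed=0, corr=0.5):
    """Complete toy table matching ``mini_schema`` (ages in months)."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=n)
    return pd.DataFrame(
        {
            "sex": rng.integers(1, 3, size=n),
            "height.a": 125 + 5.5 * z[:, 0],
            "weight.a": 26 + 4.5 * z[:, 1],
            "age.a": rng.normal(7.4 * 12, 3.0, size=n),
        }
    )
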