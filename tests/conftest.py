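import numpy as np
import pandas as pd
import pytest

from cityframe import synthetic as syn
from cityframe.correct import CompletenessFactor
from cityframe.harmonize import demo_cause_map, harmonize_records
from cityframe.population import StandardPopulation


@pytest.fixture(scope="session")
def config():
    """Default synthetic study conditions."""
    return syn.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def raw_mortality(config):
    records, ledger = syn.generate_mortality(config)
    return records, ledger


@pytest.fixture(scope="session")
def harmonized(raw_mortality):
    records, _ = raw_mortality
    table, report = harmonize_records(
        records, syn.DEMO_SEX_CODEBOOK, syn.DEMO_EDUCATION_CODEBOOK, demo_cause_map()
    )
    return table, report


@pytest.fixture(scope="session")
def country_factor(config):
    return [CompletenessFactor(country=syn.COUNTRY, value=config.completeness)]


@pytest.fixture(scope="session")
def standard():
    return StandardPopulation.demo()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_agg_table(rows):
    """Aggregated death table from (country, year, l2, age5, sex, edu, cause, observed, corrected)."""
    return pd.DataFrame(
        rows,
        columns=[
            "country", "year", "l2_code", "age5", "sex", "education",
            "cause_group", "observed_count", "corrected_count",
        ],
    )
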