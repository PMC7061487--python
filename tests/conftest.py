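import pandas as pd
import pytest

from codqc import (
    DeathTable, PopulationTable, generate_dataset, load_code_metadata,
)


def make_deaths(rows, year=2015, **extra_cols):
    """Build a DeathTable from (sex, age_group, icd_code, count) tuples."""
    df = pd.DataFrame(rows, columns=["sex", "age_group", "icd_code", "count"])
    df.insert(0, "year", year)
    for k, v in extra_cols.items():
        df[k] = v
    return DeathTable(df)


def make_population(rows, year=2015):
    """Build a PopulationTable from (sex, age_group, count) tuples."""
    df = pd.DataFrame(rows, columns=["sex", "age_group", "count"])
    df.insert(0, "year", year)
    return PopulationTable(df)


def full_population(per_band=10_000, year=2015):
    """Uniform population covering the whole ladder for both sexes."""
    from codqc import age_ladder
    rows = [(sex, band, per_band)
            for sex in ("male", "female")
            for band in age_ladder(include_unknown=False)]
    return make_population(rows, year=year)


@pytest.fixture(scope="session")
def metadata():
    return load_code_metadata()


@pytest.fixture(scope="session")
def perfect_fixture():
    """Deterministic defect-free dataset scored against its own truth."""
    return generate_dataset(seed=11)
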