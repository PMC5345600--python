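import numpy as np
import pandas as pd
import pytest

from hapbdm.genotyping import assemble_groups, filter_hybrid_samples, panel_from_table
from hapbdm.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def study_table() -> pd.DataFrame:
    """One study-scale null dataset (quota group sizes, 9% missing)."""
    return generate_dataset(SimConfig(seed=2024))


@pytest.fixture(scope="session")
def complete_table() -> pd.DataFrame:
    """Study-scale null dataset without missing calls (complete design)."""
    return generate_dataset(SimConfig(seed=2024, missing_rate=0.0))


@pytest.fixture(scope="session")
def study_groups(study_table):
    return assemble_groups(filter_hybrid_samples(study_table))


@pytest.fixture(scope="session")
def complete_groups(complete_table):
    return assemble_groups(filter_hybrid_samples(complete_table))


@pytest.fixture(scope="session")
def panel(study_table):
    return panel_from_table(study_table)


def make_table(rows, markers=("A", "B")):
    """Small genotype table from (sample_id, phenotype, cytotype, calls...) rows."""
    cols = ["sample_id", "phenotype", "cytotype", *markers]
    df = pd.DataFrame(rows, columns=cols)
    for m in markers:
        df[m] = df[m].astype(object).where(pd.notna(df[m]), np.nan)
    return df
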