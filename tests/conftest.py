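import numpy as np
import pytest

from casebias.taxonomy import build_taxonomy
from casebias.synthetic import sample_abundance_table, sample_host_data


@pytest.fixture(scope="session")
def small_taxonomy():
    return build_taxonomy([2, 3, 3, 4, 5, 4], seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """60 cases + 15 controls with genotypes, plus a 21-taxon table."""
    tax = build_taxonomy([2, 3, 3, 4, 5, 4], seed=7)
    table = sample_abundance_table(tax, 75, target_zero_fracs=0.2, seed=3)
    cohort = sample_host_data(60, 15, seed=5)
    # trim the host data to the table's samples
    table.values.index = cohort.metadata.index[:75]
    if table._own_counts is not None:
        table._own_counts.index = table.values.index
    return table, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
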