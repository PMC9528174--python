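import warnings

import numpy as np
import pytest

from bioagestack.cohort import (
    MissingnessProfile,
    default_cohort_spec,
    drop_oracle_columns,
    generate_cohort,
    inject_missing,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*IterativeImputer.*")


@pytest.fixture(scope="session")
def small_cohort():
    """400-row default cohort (oracle column retained)."""
    return generate_cohort(default_cohort_spec(400, seed=7))


@pytest.fixture(scope="session")
def mid_cohort():
    """2000-row default cohort without the oracle column."""
    return drop_oracle_columns(generate_cohort(default_cohort_spec(2000, seed=11)))


@pytest.fixture(scope="session")
def gapped_small(small_cohort):
    """Small cohort with 10% MCAR gaps plus its mask."""
    table = drop_oracle_columns(small_cohort)
    return inject_missing(table, MissingnessProfile("MCAR", global_rate=0.10), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
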