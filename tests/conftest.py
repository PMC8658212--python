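import numpy as np
import pytest

from tropref import GeneratorParams, apply_exclusions, generate_cohort
from tropref.renal import add_renal_columns


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return generate_cohort(default_params)


@pytest.fixture(scope="session")
def filtered_cohorts(default_cohort):
    """(cohort1, cohort2, report) with eGFR columns attached."""
    c1, c2, report = apply_exclusions(default_cohort)
    return add_renal_columns(c1), add_renal_columns(c2), report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
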