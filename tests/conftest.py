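import warnings

import pytest

from chmnat.datasets import (
    load_decade_summaries,
    load_missense_subjects,
    load_stability_records,
    mutation_family_variants,
)
from chmnat.simulate import CohortConfig, simulate_cohort

# variant-classification warnings are part of normal operation on odd inputs
warnings.filterwarnings("ignore", category=UserWarning, module="chmnat.cohort")


@pytest.fixture(scope="session")
def family_variants():
    """Parsed 106-family mutation spectrum."""
    return mutation_family_variants()


@pytest.fixture(scope="session")
def missense_subjects():
    """The eight missense-genotype subjects."""
    return load_missense_subjects()


@pytest.fixture(scope="session")
def decade_table():
    return load_decade_summaries()


@pytest.fixture(scope="session")
def stability_records():
    return load_stability_records()


@pytest.fixture(scope="session")
def va_cohort():
    """Default 128-subject synthetic cohort, fixed seed."""
    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def vf_cohort():
    """64-subject field-assessed synthetic cohort, fixed seed."""
    return simulate_cohort(CohortConfig.vf_study(seed=11))
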