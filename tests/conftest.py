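import numpy as np
import pytest

from equinoise import CohortConfig, simulate
from equinoise.analysis import analyze
from equinoise.equivalent_noise import lapse_correction_build
from equinoise.validation import cohort_structure_rates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lapse_table():
    """One full lapse-correction table shared by every test that corrects."""
    return lapse_correction_build(rng=np.random.default_rng(7042))


@pytest.fixture(scope="session")
def default_dataset():
    """One full default synthetic cohort (123 participants, both speeds)."""
    return simulate(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_report(default_dataset, lapse_table):
    return analyze(default_dataset, lapse_table=lapse_table)


@pytest.fixture(scope="session")
def structure_rates(lapse_table):
    """Structural-finding recovery rates over 20 seeded default cohorts.

    Session-scoped because it simulates and analyses 20 full cohorts; the
    regression-structure, interaction-power and outlier-frequency checks
    all read from this one computation.
    """
    return cohort_structure_rates(seed=2025, n_seeds=20, lapse_table=lapse_table)
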