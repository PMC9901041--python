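import pytest

from gutharvest.energy_accounting import MBD_MEAN_DIET, WD_MEAN_DIET, partition_substrates
from gutharvest.stats_report import run_pipeline
from gutharvest.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def wd_substrates():
    return partition_substrates(WD_MEAN_DIET)


@pytest.fixture(scope="session")
def mbd_substrates():
    return partition_substrates(MBD_MEAN_DIET)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-configuration synthetic cohort (n=17, seed=42)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    return run_pipeline(default_cohort)
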