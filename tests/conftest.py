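import warnings

import numpy as np
import pytest

from oculogas import datasets
from oculogas.phantom import cohort_from_table3
from oculogas.pipeline import PipelineConfig, run_case

warnings.filterwarnings("ignore", message="multiple dark components")


@pytest.fixture(scope="session")
def printed_tables():
    return {
        "patients": datasets.load_patients(),
        "outcomes": datasets.load_outcomes(),
        "gas_angle": datasets.load_gas_angle(),
    }


@pytest.fixture(scope="session")
def cohort_scenarios(printed_tables):
    return cohort_from_table3(printed_tables["gas_angle"], printed_tables["patients"])


@pytest.fixture(scope="session")
def cohort_measurements(cohort_scenarios):
    """The 16 per-case phantom measurements at noise 0 (computed once)."""
    config = PipelineConfig(seed=1, noise_sd=0.0)
    return [run_case(sc, config) for sc in cohort_scenarios]
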