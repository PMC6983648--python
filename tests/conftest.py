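import numpy as np
import pytest

from dcenirs.synthetic import (
    BolusModel,
    OpticalScene,
    PerfusionGroundTruth,
    StudyDesign,
    generate_bolus_measurement,
    generate_cohort_study,
    generate_irf,
)


@pytest.fixture(scope="session")
def scene():
    return OpticalScene()


@pytest.fixture(scope="session")
def irf(scene):
    return generate_irf(scene)


@pytest.fixture(scope="session")
def noiseless_measurement():
    """Default in-vivo protocol, shot noise off (exact round trips)."""
    return generate_bolus_measurement(noise=False)


@pytest.fixture(scope="session")
def noisy_measurement():
    return generate_bolus_measurement(seed=11)


@pytest.fixture(scope="session")
def study_table():
    table, truth = generate_cohort_study(StudyDesign(), seed=7)
    return table, truth
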