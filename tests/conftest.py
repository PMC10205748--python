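import numpy as np
import pytest

from dosewindow import PatientParameters, load_reference_patients


@pytest.fixture(scope="session")
def records():
    return {r.patient_id: r for r in load_reference_patients()}


@pytest.fixture(scope="session")
def patient2(records):
    return records[2]


@pytest.fixture(scope="session")
def patient6(records):
    return records[6]


@pytest.fixture
def fig2_params():
    """The illustrative phase-diagram parameter set (r=0.02, c=3, K=1000)."""
    return PatientParameters(r=0.02, K=1000.0, delta=0.025, c=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230523)
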