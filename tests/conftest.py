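import numpy as np
import pytest

from oralbe.compound import load_compound
from oralbe.synthetic_data import dose_event_for


@pytest.fixture(scope="session")
def amlodipine():
    return load_compound("amlodipine")


@pytest.fixture(scope="session")
def atorvastatin():
    return load_compound("atorvastatin")


@pytest.fixture(scope="session")
def amlodipine_dose(amlodipine):
    return dose_event_for(amlodipine, "single")


@pytest.fixture(scope="session")
def atorvastatin_dose(atorvastatin):
    return dose_event_for(atorvastatin, "single")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
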