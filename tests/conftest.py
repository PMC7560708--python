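import random

import pytest
from hypothesis import HealthCheck, settings

from samcliff import standardize

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMILES = {
    "benzene": "c1ccccc1",
    "pyridine": "c1ccncc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "furan": "c1ccoc1",
    "thiophene": "c1ccsc1",
    "2-picoline": "Cc1ccccn1",
    "3-picoline": "Cc1cccnc1",
    "4-picoline": "Cc1ccncc1",
    "pyridazine": "c1ccnnc1",
    "pyrimidine": "c1cncnc1",
    "pyrazine": "c1cnccn1",
    "toluene": "Cc1ccccc1",
    "ethane": "CC",
    "ethanol": "CCO",
}


@pytest.fixture(scope="session")
def mols():
    """Named standardized molecules used across tests."""
    return {name: standardize(smi, name) for name, smi in SMILES.items()}


@pytest.fixture()
def rng():
    return random.Random(20240917)
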