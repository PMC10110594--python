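"""Shared fixtures: synthetic systems and (expensive) FIC calibrations.

Calibrations are session-scoped so the model-level tests and the acceptance
suite share them instead of re-running the iterative balancing.
"""

import numpy as np
import pytest

from neuroentropy import (
    ModelParameters,
    SyntheticSpec,
    calibrate_fic,
    generate_connectome,
    generate_metadata,
    generate_receptor_map,
)

PARAMS = ModelParameters(seed=7)


@pytest.fixture(scope="session")
def spec10():
    return SyntheticSpec(n_regions=10, density=0.5, seed=42)


@pytest.fixture(scope="session")
def spec30():
    return SyntheticSpec(n_regions=30, density=0.3, seed=42)


@pytest.fixture(scope="session")
def con10(spec10):
    return generate_connectome(spec10)


@pytest.fixture(scope="session")
def rec10(spec10, con10):
    return generate_receptor_map(spec10, con10)


@pytest.fixture(scope="session")
def meta10(spec10, con10):
    return generate_metadata(spec10, con10)


@pytest.fixture(scope="session")
def con30(spec30):
    return generate_connectome(spec30)


@pytest.fixture(scope="session")
def rec30(spec30, con30):
    return generate_receptor_map(spec30, con30)


@pytest.fixture(scope="session")
def params():
    return PARAMS


@pytest.fixture(scope="session")
def cal10(con10, rec10, params):
    return calibrate_fic(con10, rec10, params)


@pytest.fixture(scope="session")
def cal30(con30, rec30, params):
    return calibrate_fic(con30, rec30, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
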