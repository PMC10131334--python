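"""Shared fixtures: one synthetic study powers most of the suite."""

import pytest

from imdnet.pathways import build_index
from imdnet.profiles import build_matrix
from imdnet.simulate import SimulationConfig, SyntheticStudy


@pytest.fixture(scope="session")
def study() -> SyntheticStudy:
    return SyntheticStudy(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def index(study):
    return build_index(study.pathways)


@pytest.fixture(scope="session")
def matrix(study):
    return build_matrix(study.profiles(), "1-5y")
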