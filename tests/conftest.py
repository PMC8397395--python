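import numpy as np
import pytest

from asdsol import ChiModel, ComponentConstants, FHModel
from asdsol.datasets import nimesulide_kollidon_constants


@pytest.fixture(scope="session")
def constants() -> ComponentConstants:
    """Published pure-component constants of the reference drug-polymer pair."""
    return nimesulide_kollidon_constants("ambient")


@pytest.fixture(scope="session")
def constants_50mpa() -> ComponentConstants:
    return nimesulide_kollidon_constants("50mpa")


@pytest.fixture
def fh_model_ab(constants) -> FHModel:
    """A chi(T) = A + B/T liquidus with realistic parameters."""
    return FHModel(
        constants=constants,
        chi_model=ChiModel(kind="linear_in_invT", a_chi=6.7, b_chi=-3000.0),
    )


@pytest.fixture
def fh_model_const(constants) -> FHModel:
    return FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=-1.2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
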