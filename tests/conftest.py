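import numpy as np
import pytest

from tissuemech import CanonicalLayout, ModelParams
from tissuemech.experiments import steady_state
from tissuemech.geometry import circle
from tissuemech.model import CrossSection, TissueLoop


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_layout() -> CanonicalLayout:
    return CanonicalLayout()


def isolated_loop_section(radius: float = 0.8, n: int = 50,
                          center=(0.0, 50.0)) -> CrossSection:
    """A single tissue loop far away from a minimal (inert) yolk wall."""
    loop = TissueLoop("NT", circle(center, radius, n))
    yolk = np.array([[0.0, 0.0], [0.05, 0.0]])
    return CrossSection(tissues=[loop], yolk=yolk)


@pytest.fixture(scope="session")
def wt_state(default_layout):
    return steady_state(100.0, 10.0, layout=default_layout)


@pytest.fixture(scope="session")
def tension_state(default_layout):
    """High-stiffness preset used for tension-map analyses."""
    return steady_state(200.0, 10.0, layout=default_layout)
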