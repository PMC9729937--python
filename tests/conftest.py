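import numpy as np
import pytest

from metrodose import GrowthParams, HillParams, PopulationState

#: Reference curve: the doxorubicin response of the sensitive tumor line
#: (EC50 3.2 uM, Hill coefficient 2, full plateaus).
TUMOR_EC50 = 3.2
HEALTHY_EC50 = 0.052


@pytest.fixture
def tumor_curve() -> HillParams:
    return HillParams(ec50=TUMOR_EC50, hill_coeff=2.0)


@pytest.fixture
def healthy_curve() -> HillParams:
    return HillParams(ec50=HEALTHY_EC50, hill_coeff=2.0)


@pytest.fixture
def growth() -> GrowthParams:
    # resistant clones grow at 20% of the sensitive rate
    return GrowthParams.from_ratio(0.2)


@pytest.fixture
def mixed_state() -> PopulationState:
    return PopulationState(n_sensitive=5e4, n_resistant=5e4)


@pytest.fixture
def log_doses() -> np.ndarray:
    return np.geomspace(0.05, 100.0, 8)
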