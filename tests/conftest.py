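import numpy as np
import pytest

from qsbiofilm import (
    ModelVariant,
    SimConfig,
    build_combined,
    build_phase2,
    build_phase3,
    simulate_ode,
)
from qsbiofilm.fixtures import make_golden_nets
from qsbiofilm.models import phase3_core


@pytest.fixture(scope="session")
def golden():
    return make_golden_nets()


@pytest.fixture(scope="session")
def phase2_net():
    return build_phase2()


@pytest.fixture(scope="session")
def phase3_net():
    return build_phase3(ModelVariant.phase3(THR_open=10))


@pytest.fixture(scope="session")
def phase3_core_net(phase3_net):
    return phase3_core(phase3_net)


@pytest.fixture(scope="session")
def combined_net():
    return build_combined()


@pytest.fixture(scope="session")
def phase2_trace(phase2_net):
    """The RK4 validation trace: 10,000 recorded points over 10,000 time
    units (shared across tests; ~15 s to produce)."""
    cfg = SimConfig(t_end=10000, n_record=10000, method="ode_rk4", h=0.05)
    return simulate_ode(phase2_net, cfg)
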