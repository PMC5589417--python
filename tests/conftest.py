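import numpy as np
import pytest

from silentwm.network import NetworkParams, RingNetwork
from silentwm.protocol import StimulusSchedule, build_schedule


@pytest.fixture(scope="session")
def default_params() -> NetworkParams:
    return NetworkParams()


@pytest.fixture(scope="session")
def tame_params() -> NetworkParams:
    """Low recurrent density: no spontaneous reignition at any mask
    amplitude; smooth dynamics for integrator checks."""
    n = 100
    return NetworkParams(n_neurons=n, rho=0.06 * n / (2 * np.pi))


@pytest.fixture(scope="session")
def silent_trace(default_params):
    """Noiseless trial in the silent maintenance regime (mask above the
    critical amplitude), shared across tests that only read it."""
    sched = build_schedule(0.0, A_mask=65.0)
    trace = RingNetwork(default_params).run(sched, noise=False, decimate=4)
    return sched, trace
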