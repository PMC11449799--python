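import numpy as np
import pytest

from twinephys.core import StepProtocol
from twinephys.synth import (
    excitable_preset,
    simulate_current_clamp,
    simulate_voltage_clamp,
)

VC_STEPS = np.arange(-90.0, 81.0, 10.0)


@pytest.fixture(scope="session")
def excitable_params():
    return excitable_preset(seed=1)


@pytest.fixture(scope="session")
def excitable_sweepset(excitable_params):
    """Full 20-step current-clamp family of the spiking preset."""
    return simulate_current_clamp(excitable_params, StepProtocol(n_steps=20))


@pytest.fixture(scope="session")
def vclamp_sweepset(excitable_params):
    """Voltage-clamp family -90..80 mV in 10 mV steps."""
    return simulate_voltage_clamp(excitable_params, VC_STEPS)


def refractory_peak_oracle(t_s, v, min_v=0.0, refractory_ms=2.0):
    """Independent spike counter: local maxima above ``min_v`` separated by
    at least the refractory interval.  Plain loop, no scipy."""
    idx = []
    last_t = -np.inf
    for k in range(1, len(v) - 1):
        if v[k] > min_v and v[k] >= v[k - 1] and v[k] > v[k + 1]:
            if (t_s[k] - last_t) * 1e3 >= refractory_ms:
                idx.append(k)
                last_t = t_s[k]
    return idx
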