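import numpy as np
import pytest
from hypothesis import settings

from firecycle import ModelParams, integrate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_params():
    return ModelParams()


@pytest.fixture(scope="session")
def base_traj(base_params):
    """The 20-year base run at default resolution, shared across tests."""
    return integrate(base_params, horizon=20.0, dt=1.0 / 64.0)


@pytest.fixture(scope="session")
def firefree_params():
    """No natural or human ignition: the burn-free subsystem."""
    return ModelParams(i_n=0.0, ih0=0.0)


def make_sine_trajectory(period=4.0, horizon=20.0, dt=1.0 / 64.0, amplitude=1.0):
    """Synthetic trajectory whose burn-rate series is a pure sine (for
    exercising the oscillation diagnostics on a known signal)."""
    from firecycle.simulate import Trajectory

    t = np.arange(int(round(horizon / dt)) + 1) * dt
    b = amplitude * np.sin(2.0 * np.pi * t / period) + amplitude
    zero = np.zeros_like(t)
    return Trajectory(
        t=t, S=0.5 + zero, F=0.4 + zero, V=0.4 + zero, Bbar=zero.copy(),
        cumB=np.concatenate(([0.0], np.cumsum((b[1:] + b[:-1]) / 2.0 * dt))),
        B=b, i_h=zero.copy(), gamma_f=zero.copy(), gamma_s=zero.copy(),
    )
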