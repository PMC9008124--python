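import numpy as np
import pytest

from cspkinetics import build_fcrn_model, default_grid, solve


@pytest.fixture(scope="session")
def model():
    return build_fcrn_model()


@pytest.fixture(scope="session")
def traj(model):
    return solve(model, default_grid())


def random_state(params, rng):
    """A random positive state respecting the FcRn conservation law."""
    cp0 = params.Dose / params.Vp
    Cp = cp0 * 10 ** rng.uniform(-3, 0)
    Ce = cp0 * 10 ** rng.uniform(-6, 0)
    frac = rng.uniform(0.01, 0.99)
    return np.array([Cp, Ce, params.FcRn0 * (1 - frac), params.FcRn0 * frac])
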