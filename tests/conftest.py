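import numpy as np
import pytest

from spheropk import pk
from spheropk.render import RenderParams
from spheropk.simulate import init_spheroid


@pytest.fixture(scope="session")
def calibrated_profile():
    """One 24-h dosing cycle: ramp to 50 µM at 1.5 h, stepwise decay
    calibrated so the cycle average equals the AUC-matched 9.3 µM."""
    rate = pk.calibrate_decay_to_constant(50.0, 1.5, 12, 9.3)
    return pk.build_profile(50.0, 1.5, 12, rate)


@pytest.fixture(scope="session")
def small_state():
    """A relaxed ~550-cell spheroid (70 µm) used by several tests."""
    return init_spheroid(70.0, 3.5, seed=7)


@pytest.fixture(scope="session")
def small_render_params():
    return RenderParams(field_px=128, n_z=51)


@pytest.fixture(scope="session")
def small_stack(small_state, small_render_params):
    """Default-noise render of the small spheroid."""
    from spheropk.render import render

    return render(small_state, small_render_params, np.random.default_rng(11))
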