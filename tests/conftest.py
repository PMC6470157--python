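import numpy as np
import pytest

import esomech as em


@pytest.fixture(scope="session")
def vehicle():
    return em.vehicle_params()


@pytest.fixture(scope="session")
def three_cycle():
    return em.three_cycle_protocol()


@pytest.fixture(scope="session")
def noiseless_trace(three_cycle, vehicle):
    """Default three-cycle simulation without instrument noise."""
    return em.simulate_trace(three_cycle, vehicle, noise_sd_mN=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_curves(noiseless_trace, three_cycle, vehicle):
    segs = em.segment_steps(noiseless_trace, three_cycle)
    return em.build_cycle_curves(segs, vehicle.geometry)


def curve_for(curves, cycle, direction="lengthen"):
    for c in curves:
        if c.cycle_index == cycle and c.direction == direction:
            return c
    raise LookupError(f"no curve for cycle {cycle} {direction}")


@pytest.fixture(scope="session")
def get_curve():
    return curve_for
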