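"""Shared fixtures: cached pathway runs and reference networks."""

from __future__ import annotations

import numpy as np
import pytest

from rbc_atp import (
    PathwayParameters,
    StimulusProtocol,
    calibrate_release,
    default_network_fixture,
    prescribed_linear_saturation,
    simulate_pathway,
    single_capillary_fixture,
)


@pytest.fixture(scope="session")
def params():
    return PathwayParameters()


@pytest.fixture(scope="session")
def anchor_traj(params):
    """Baseline run: 40 ms desaturation pulse to 15.7% sO2."""
    return simulate_pathway(params, StimulusProtocol.pulse(0.157))


@pytest.fixture(scope="session")
def calibration(params):
    return calibrate_release(params)


@pytest.fixture(scope="session")
def pulse_release(params):
    """Memoized total release for 40 ms pulses (keyed by sO2 and overrides)."""
    cache: dict = {}

    def run(sO2: float, **overrides) -> float:
        key = (sO2, tuple(sorted(overrides.items())))
        if key not in cache:
            p = params.replace(**overrides) if overrides else params
            traj = simulate_pathway(p, StimulusProtocol.pulse(sO2))
            cache[key] = traj.total_release()
        return cache[key]

    return run


@pytest.fixture(scope="session")
def net208():
    return default_network_fixture(seed=42)


@pytest.fixture(scope="session")
def linear_sat208(net208):
    return prescribed_linear_saturation(net208, 0.63, 0.17)


@pytest.fixture(scope="session")
def single_cap():
    return single_capillary_fixture()


@pytest.fixture(scope="session")
def const_sat_single(single_cap):
    """Constant 50% saturation on the single-capillary fixture."""
    return prescribed_linear_saturation(single_cap, 0.5, 0.5)
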