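"""Shared fixtures: the mouse study conditions and converged steady states."""

import math

import numpy as np
import pytest
from hypothesis import settings

import psmclock as pc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TWO_PI = 2.0 * math.pi

MOUSE_LAM = 0.266
MOUSE_T0 = 130.0
MOUSE_BETA = 1.0 / 7.0
MOUSE_PHI_WIDTH_FRAC = MOUSE_LAM / (1.0 + MOUSE_LAM)  # 0.21011...


@pytest.fixture(scope="session")
def mouse_clock():
    return pc.ClockParams(t0=MOUSE_T0, lam=MOUSE_LAM, xi=0.0)


@pytest.fixture(scope="session")
def mouse_gradient(mouse_clock):
    return pc.linear_gradient(mouse_clock)


@pytest.fixture(scope="session")
def quadratic_gradient():
    """Monotone nonlinear fixture: T(x) = 130 (1 + 0.266 x^2), 101 samples."""
    xs = np.linspace(0.0, 1.0, 101)
    return pc.tabulated_gradient(list(zip(xs, MOUSE_T0 * (1.0 + MOUSE_LAM * xs**2))))


@pytest.fixture(scope="session")
def const_length_result(mouse_clock):
    """Continuum constant-length steady state at the mouse conditions."""
    return pc.steady_profile_constant_length(mouse_clock, beta=MOUSE_BETA)


@pytest.fixture(scope="session")
def no_growth_result(mouse_clock):
    """Continuum no-growth fixed point at the mouse conditions."""
    return pc.steady_profile_no_growth(
        mouse_clock, phi_before=TWO_PI, phi_width=0.21 * TWO_PI, grid_size=1001
    )


@pytest.fixture(scope="session")
def mouse_regime_70():
    return pc.RegimeParams(rule="timed", ts=MOUSE_T0, tg=13.0, n=70, beta=MOUSE_BETA)


@pytest.fixture(scope="session")
def discrete_steady_70(mouse_clock, mouse_regime_70):
    return pc.run_to_steady_state(mouse_clock, mouse_regime_70)
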