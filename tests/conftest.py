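"""Shared fixtures: the motivating two-arm staggered-entry designs.

Boundary calibration is the expensive step, so calibrated designs are
session-scoped.  The reference design adds a second arm halfway through
the first arm's recruitment (addition ratio 1), targets a one-sided
familywise error of 2.5% with binding triangular bounds, and a clinically
relevant effect of -log(0.69) on the benefit scale with unit variance.
"""

import numpy as np
import pytest

from platformtrial import calibrate, make_standard_layout

THETA_PRIME = -np.log(0.69)
ALPHA = 0.025


@pytest.fixture(scope="session")
def theta_prime():
    return THETA_PRIME


@pytest.fixture(scope="session")
def pairwise_design():
    """The 80%-pairwise-power design: n = 76/stage, second arm at n(2) = 76."""
    layout = make_standard_layout(2, 2, 76, n_add=[0, 76], sigma=1.0,
                                  theta_prime=THETA_PRIME)
    bounds = calibrate(layout, "triangular", ALPHA, binding=True)
    return layout, bounds


@pytest.fixture(scope="session")
def conjunctive_design(pairwise_design):
    """The 80%-conjunctive-power design: n = 96, same boundary scale.

    The addition ratio (1) and shape are unchanged, so the calibrated
    boundaries carry over from the pairwise design.
    """
    _, bounds = pairwise_design
    layout = make_standard_layout(2, 2, 96, n_add=[0, 96], sigma=1.0,
                                  theta_prime=THETA_PRIME)
    return layout, bounds


@pytest.fixture(scope="session")
def small_design():
    """A cheap single-stage two-arm design for fast property checks."""
    layout = make_standard_layout(2, 1, 40, n_add=[0, 20], sigma=1.0,
                                  theta_prime=0.5)
    bounds = calibrate(layout, "triangular", 0.05, binding=True)
    return layout, bounds
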