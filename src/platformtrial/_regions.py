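"""Internal assembly of stopping-event rectangles.

Every error-rate, power and outcome probability in the package is the
probability that the stagewise statistics fall in an axis-aligned rectangle:
each arm continues (l < Z < u) through the stages before its stopping stage
and then exits below l (futility) or above u (efficacy).  Under effect
theta_k the statistic at (k, j) is shifted by theta_k * sqrt(I_{k,j}), so
the shift is subtracted from the limits and the probability evaluated under
the zero-mean law.
"""

from __future__ import annotations

import math

import numpy as np

from ._mvn import rectangle_probability
from .correlation import correlation_matrix, information
from .layout import PlatformLayout

FUTILITY, EFFICACY = 0, 1


def arm_coords(layout: PlatformLayout, U_k, L_k, k: int, j_stop: int, exit_dir: int,
               theta: float):
    """(index, lower, upper) coordinates for one arm's stopping event."""
    idx, lo, hi = [], [], []
    for j in range(1, j_stop):
        s = theta * math.sqrt(information(layout, k, j))
        idx.append((k, j))
        lo.append(L_k[j - 1] - s)
        hi.append(U_k[j - 1] - s)
    s = theta * math.sqrt(information(layout, k, j_stop))
    idx.append((k, j_stop))
    if exit_dir == FUTILITY:
        lo.append(-np.inf)
        hi.append(L_k[j_stop - 1] - s)
    else:
        lo.append(U_k[j_stop - 1] - s)
        hi.append(np.inf)
    return idx, lo, hi


def joint_probability(layout: PlatformLayout, arm_events) -> float:
    """Probability that every listed arm realises its stopping event.

    ``arm_events`` is an iterable of ``(k, U_k, L_k, j_stop, exit_dir,
    theta)``; arms not listed are marginalised out of the joint law.
    """
    idx, lo, hi = [], [], []
    for k, U_k, L_k, j_stop, exit_dir, theta in arm_events:
        i, l, h = arm_coords(layout, U_k, L_k, k, j_stop, exit_dir, theta)
        idx.extend(i)
        lo.extend(l)
        hi.extend(h)
    return rectangle_probability(lo, hi, correlation_matrix(layout, idx))
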