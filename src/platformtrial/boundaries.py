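"""Stopping-boundary families and familywise-error calibration.

Boundary shapes are one-parameter families indexed by a scale ``a``: the
triangular test (continuation region narrowing linearly in information),
Pocock (flat) and O'Brien-Fleming (steeply decreasing) efficacy bounds with
a zero interim futility bound.  Calibration solves for the single ``a`` at
which the familywise error rate under the global null equals the target
alpha, using the joint multivariate-normal law of all stagewise statistics.

With binding futility bounds the lower boundary is enforced in the error
calculation; for nonbinding bounds the interim lower limits are dropped
(set to -infinity) so that overriding a futility stop cannot inflate the
error rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from ._mvn import rectangle_probability
from ._regions import FUTILITY, joint_probability
from .correlation import correlation_matrix, default_index
from .layout import PlatformLayout

SHAPES = ("triangular", "pocock", "obrien_fleming")

#: calibration solves |FWER - alpha| to this tolerance
CALIBRATION_TOL = 1e-6


@dataclass(frozen=True)
class BoundarySet:
    """Per-arm upper/lower stopping boundaries from a one-parameter shape."""

    shape: str
    a: float
    U: tuple          # per-arm tuples of efficacy bounds u_{k,1..J_k}
    L: tuple          # per-arm tuples of futility bounds l_{k,1..J_k}
    binding: bool = True

    def __post_init__(self):
        object.__setattr__(self, "U", tuple(tuple(float(v) for v in row) for row in self.U))
        object.__setattr__(self, "L", tuple(tuple(float(v) for v in row) for row in self.L))
        for U_k, L_k in zip(self.U, self.L):
            if len(U_k) != len(L_k):
                raise ValueError("upper and lower boundaries must align per stage")
            if any(l > u for l, u in zip(L_k, U_k)):
                raise ValueError("lower boundary exceeds upper boundary")
            if L_k[-1] != U_k[-1]:
                raise ValueError("final analysis must force a decision (l_J = u_J)")

    def to_dict(self) -> dict:
        return {"shape": self.shape, "a": self.a,
                "U": [list(r) for r in self.U], "L": [list(r) for r in self.L],
                "binding": self.binding}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundarySet":
        return cls(shape=d["shape"], a=d["a"], U=d["U"], L=d["L"],
                   binding=d["binding"])


def shape_bounds(shape: str, a: float, J: int):
    """Upper and lower boundaries for one arm under the named shape.

    triangular:      u_j = a (1 + j/J) / sqrt(j),  l_j = a (-1 + 3 j/J) / sqrt(j)
    pocock:          u_j = a,            interim l_j = 0
    obrien_fleming:  u_j = a sqrt(J/j),  interim l_j = 0

    The final lower bound always equals the final upper bound so the last
    analysis forces a decision.
    """
    if a <= 0:
        raise ValueError("scale parameter a must be positive")
    if J < 1:
        raise ValueError("need at least one stage")
    if shape == "triangular":
        U = [a * (1 + j / J) / math.sqrt(j) for j in range(1, J + 1)]
        L = [a * (-1 + 3 * j / J) / math.sqrt(j) for j in range(1, J + 1)]
    elif shape == "pocock":
        U = [a] * J
        L = [0.0] * J
    elif shape == "obrien_fleming":
        U = [a * math.sqrt(J / j) for j in range(1, J + 1)]
        L = [0.0] * J
    else:
        raise ValueError(f"unknown boundary shape {shape!r}; choose from {SHAPES}")
    L[-1] = U[-1]
    return tuple(U), tuple(L)


def bounds_for_layout(layout: PlatformLayout, shape: str, a: float,
                      binding: bool = True) -> BoundarySet:
    """Common-shape BoundarySet matching the layout's per-arm stage counts."""
    UL = [shape_bounds(shape, a, J_k) for J_k in layout.J]
    return BoundarySet(shape=shape, a=a, U=tuple(u for u, _ in UL),
                       L=tuple(l for _, l in UL), binding=binding)


def fwer_global_null(layout: PlatformLayout, bounds: BoundarySet) -> float:
    """Familywise error rate under the global null hypothesis.

    One minus the probability that every arm is stopped for futility,
    summed over all disjoint combinations of per-arm stopping stages.  For
    nonbinding bounds the interim futility limits are ignored, which
    collapses the sum to a single rectangle: no arm ever exceeds its
    efficacy bound.
    """
    if len(bounds.U) != layout.K:
        raise ValueError("boundary set does not match the number of arms")
    for k in range(layout.K):
        if len(bounds.U[k]) != layout.J[k]:
            raise ValueError(f"arm {k + 1}: boundary length does not match J_k")
    if not bounds.binding:
        idx = default_index(layout)
        hi = [bounds.U[k - 1][j - 1] for k, j in idx]
        lo = [-np.inf] * len(idx)
        return 1.0 - rectangle_probability(lo, hi, correlation_matrix(layout, idx))
    total = 0.0
    for stages in itertools.product(*[range(1, J_k + 1) for J_k in layout.J]):
        total += joint_probability(
            layout,
            [(k, bounds.U[k - 1], bounds.L[k - 1], stages[k - 1], FUTILITY, 0.0)
             for k in range(1, layout.K + 1)],
        )
    return 1.0 - total


def calibrate(layout: PlatformLayout, shape: str, alpha: float,
              binding: bool = True) -> BoundarySet:
    """Solve for the boundary scale at which FWER(global null) = alpha.

    The error rate is monotone decreasing in ``a``; a bracketing scalar
    root-find locates the unique solution.  Raises if no bracket can be
    found over a wide scan of scales.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    def excess(a: float) -> float:
        return fwer_global_null(layout, bounds_for_layout(layout, shape, a, binding)) - alpha

    lo, hi = 0.25, 2.5
    f_lo, f_hi = excess(lo), excess(hi)
    while f_hi > 0 and hi < 20:
        lo, f_lo = hi, f_hi
        hi *= 1.6
        f_hi = excess(hi)
    while f_lo < 0 and lo > 1e-3:
        hi, f_hi = lo, f_lo
        lo /= 2
        f_lo = excess(lo)
    if f_lo < 0 or f_hi > 0:
        raise RuntimeError(
            f"could not bracket the boundary scale in [{lo:.4g}, {hi:.4g}] "
            f"(FWER excess {f_lo:.3g} .. {f_hi:.3g})")
    a = brentq(excess, lo, hi, xtol=1e-9, rtol=1e-12)
    return bounds_for_layout(layout, shape, a, binding)


def single_stage_scale(shape: str, alpha: float) -> float:
    """Closed-form scale for a one-arm, one-stage design (sanity anchor)."""
    z = norm.ppf(1 - alpha)
    return z / 2 if shape == "triangular" else z
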