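"""Power definitions and sample-size search.

Three notions of power are supported for a design in which every arm is
tested to its own conclusion:

* pairwise  — probability a given arm with effect theta is declared
  superior; depends only on that arm's own boundaries and information.
* conjunctive — probability that *all* arms whose true effect reaches the
  clinically relevant threshold theta' are declared superior; equal to 1
  when no arm reaches the threshold.
* disjunctive — probability that at least one arm is declared superior;
  reduces to the familywise error rate under the global null.

An effect of ``-inf`` is admitted symbolically: such an arm always stops
for futility at its first analysis and contributes no efficacy events.

Sample-size search increases the per-stage size n until the requested power
meets its target.  When arms join at fixed ratios of n the boundaries are
invariant in n and are calibrated once; when the addition counts are fixed
absolute patient numbers, the allocation ratios change with n and the
boundaries are recalibrated at every candidate n (iterative scheme for
predefined addition counts).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._regions import EFFICACY, FUTILITY, joint_probability
from .boundaries import BoundarySet, calibrate
from .layout import PlatformLayout, make_standard_layout

POWER_TYPES = ("pairwise", "conjunctive", "disjunctive")


@dataclass(frozen=True)
class PowerRequest:
    """A power target: which notion of power, the level, and the effects."""

    type: str
    target: float
    Theta: tuple | None = None

    def __post_init__(self):
        if self.type not in POWER_TYPES:
            raise ValueError(f"power type must be one of {POWER_TYPES}")
        if not 0 < self.target < 1:
            raise ValueError("power target must lie in (0, 1)")
        if self.Theta is not None:
            object.__setattr__(self, "Theta", tuple(float(t) for t in self.Theta))


def _effects(layout: PlatformLayout, Theta) -> np.ndarray:
    theta = np.asarray(Theta, dtype=float)
    if theta.size != layout.K:
        raise ValueError("Theta must have one effect per arm")
    return theta


def pairwise_power(layout: PlatformLayout, bounds: BoundarySet, k: int,
                   theta_k: float) -> float:
    """Probability arm k is declared superior, given its effect.

    Independent of every other arm's effect: the sum over arm k's stopping
    stages of the within-arm continuation-then-efficacy probabilities.
    """
    if not 1 <= k <= layout.K:
        raise ValueError(f"invalid arm {k}")
    if theta_k == -np.inf:
        return 0.0
    U_k, L_k = bounds.U[k - 1], bounds.L[k - 1]
    return sum(
        joint_probability(layout, [(k, U_k, L_k, j_stop, EFFICACY, theta_k)])
        for j_stop in range(1, layout.J[k - 1] + 1)
    )


def _all_efficacy_sum(layout: PlatformLayout, bounds: BoundarySet,
                      arms: Sequence[int], theta: np.ndarray) -> float:
    """P(every arm in ``arms`` exits through its efficacy bound)."""
    total = 0.0
    for stages in itertools.product(*[range(1, layout.J[k - 1] + 1) for k in arms]):
        total += joint_probability(
            layout,
            [(k, bounds.U[k - 1], bounds.L[k - 1], j_stop, EFFICACY, theta[k - 1])
             for k, j_stop in zip(arms, stages)],
        )
    return total


def _all_futility_sum(layout: PlatformLayout, bounds: BoundarySet,
                      arms: Sequence[int], theta: np.ndarray) -> float:
    """P(every arm in ``arms`` exits through its futility bound)."""
    total = 0.0
    for stages in itertools.product(*[range(1, layout.J[k - 1] + 1) for k in arms]):
        total += joint_probability(
            layout,
            [(k, bounds.U[k - 1], bounds.L[k - 1], j_stop, FUTILITY, theta[k - 1])
             for k, j_stop in zip(arms, stages)],
        )
    return total


def conjunctive_power(layout: PlatformLayout, bounds: BoundarySet,
                      Theta: Sequence[float], theta_prime: float | None = None) -> float:
    """Probability all arms with effect >= theta' are declared superior.

    Arms below the clinically relevant threshold are marginalised out; if no
    arm reaches the threshold there is nothing to find and the power is 1.
    The guarantee behind sizing at Theta' = (theta', ..., theta') is that
    this probability is minimised there over all Theta.
    """
    theta = _effects(layout, Theta)
    thr = layout.theta_prime if theta_prime is None else theta_prime
    relevant = [k for k in range(1, layout.K + 1) if theta[k - 1] >= thr - 1e-12]
    if not relevant:
        return 1.0
    return _all_efficacy_sum(layout, bounds, relevant, theta)


def rejection_probability_any(layout: PlatformLayout, bounds: BoundarySet,
                              arms: Sequence[int], Theta: Sequence[float]) -> float:
    """P(at least one arm in ``arms`` is declared superior | Theta).

    Because the final analysis forces a decision, this is one minus the
    probability that every listed arm exits through its futility bound.
    Evaluated over the subset S of true nulls it is the familywise error
    of that null configuration, which strong control bounds by alpha.
    """
    theta = _effects(layout, Theta)
    live = [k for k in arms if theta[k - 1] > -np.inf]
    if not live:
        return 0.0
    return 1.0 - _all_futility_sum(layout, bounds, live, theta)


def disjunctive_power(layout: PlatformLayout, bounds: BoundarySet,
                      Theta: Sequence[float]) -> float:
    """Probability at least one arm is declared superior.

    Equals the familywise error rate when evaluated at the global null.
    """
    return rejection_probability_any(layout, bounds, range(1, layout.K + 1), Theta)


def power_table(layout: PlatformLayout, bounds: BoundarySet,
                Theta: Sequence[float]) -> dict:
    """All three powers at one effect vector (one report row)."""
    theta = _effects(layout, Theta)
    return {
        **{f"pairwise_{k}": pairwise_power(layout, bounds, k, theta[k - 1])
           for k in range(1, layout.K + 1)},
        "conjunctive": conjunctive_power(layout, bounds, theta),
        "disjunctive": disjunctive_power(layout, bounds, theta),
    }


# -- sample-size search ------------------------------------------------------


def _requested_power(layout: PlatformLayout, bounds: BoundarySet,
                     request: PowerRequest) -> float:
    theta = (np.full(layout.K, layout.theta_prime) if request.Theta is None
             else _effects(layout, request.Theta))
    if request.type == "pairwise":
        return min(pairwise_power(layout, bounds, k, theta[k - 1])
                   for k in range(1, layout.K + 1))
    if request.type == "conjunctive":
        return conjunctive_power(layout, bounds, theta)
    return disjunctive_power(layout, bounds, theta)


def find_n(K: int, J: int, r_add: Sequence[float], shape: str, alpha: float,
           request: PowerRequest, *, sigma: float = 1.0, theta_prime: float,
           binding: bool = True, n_cap: int = 10_000,
           method: str = "bisect") -> tuple:
    """Smallest per-stage n meeting the power target, additions at fixed ratios.

    With addition counts proportional to n (``n_add = r_add * n``) the
    correlation structure, and hence the calibrated boundaries, do not
    depend on n; the boundaries are calibrated once on a scale-free layout
    and n is then the smallest integer whose power reaches the target.

    ``method="scan"`` steps n upward one patient at a time;
    ``method="bisect"`` exploits monotonicity of power in n and returns the
    same minimal n.  Returns ``(layout, bounds)``.
    """
    ratio_layout = make_standard_layout(K, J, n1=1.0, n_add=list(r_add),
                                        sigma=sigma, theta_prime=theta_prime)
    bounds = calibrate(ratio_layout, shape, alpha, binding)

    def power_at(n: int) -> float:
        lay = make_standard_layout(K, J, n1=n, r_add=r_add,
                                   sigma=sigma, theta_prime=theta_prime)
        return _requested_power(lay, bounds, request)

    if method == "scan":
        n = 1
        while power_at(n) < request.target:
            n += 1
            if n > n_cap:
                raise RuntimeError(f"power target not reached below n = {n_cap}")
    elif method == "bisect":
        hi = 8
        while power_at(hi) < request.target:
            hi *= 2
            if hi > 2 * n_cap:
                raise RuntimeError(f"power target not reached below n = {n_cap}")
        lo = hi // 2 if hi > 8 else 0
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if mid == 0 or power_at(mid) < request.target:
                lo = mid
            else:
                hi = mid
        n = hi
    else:
        raise ValueError("method must be 'scan' or 'bisect'")
    layout = make_standard_layout(K, J, n1=n, r_add=r_add,
                                  sigma=sigma, theta_prime=theta_prime)
    return layout, bounds


def find_n_fixed_addition(K: int, J: int, n_add: Sequence[float], shape: str,
                          alpha: float, request: PowerRequest, *,
                          sigma: float = 1.0, theta_prime: float,
                          binding: bool = True, n_start: int | None = None,
                          n_cap: int = 10_000) -> tuple:
    """Iterative sizing when arms join at fixed absolute control counts.

    Because fixed addition counts do not scale with n, the allocation
    ratios — and with them the calibrated boundaries — change at every
    candidate n.  Starting from the size required with no staggering, the
    boundaries are recalibrated at the true addition counts and n is
    increased one patient at a time until the requested power holds.

    ``n_start`` overrides the no-staggering starting size (useful to warm
    start a sweep over addition counts; the loop only ever increases n, so
    any n at or below the answer yields the same result).
    """
    if n_start is None:
        base_layout, _ = find_n(K, J, [0.0] * K, shape, alpha, request,
                                sigma=sigma, theta_prime=theta_prime,
                                binding=binding, n_cap=n_cap)
        n = int(round(base_layout.n1))
    else:
        n = int(n_start)
    while True:
        layout = make_standard_layout(K, J, n1=n, n_add=list(n_add),
                                      sigma=sigma, theta_prime=theta_prime)
        bounds = calibrate(layout, shape, alpha, binding)
        if _requested_power(layout, bounds, request) >= request.target:
            return layout, bounds
        n += 1
        if n > n_cap:
            raise RuntimeError(
                f"power target not reached below n = {n_cap} for fixed "
                f"addition counts {tuple(n_add)}")
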