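"""Comparison of a platform design against running separate trials.

Two error conventions are considered for K separate two-arm trials.  Under
Setting 1 the type-I error is controlled across the family, so each trial
runs at alpha_k = 1 - (1 - alpha)^(1/K); under Setting 2 each trial keeps
the full alpha.  When the comparison targets conjunctive power, each
separate trial is powered at (1 - beta)^(1/K) so that all K independent
trials succeed with probability 1 - beta.

The crossover search locates the smallest inter-arm addition gap at which
the platform design stops being the smaller trial: for each candidate gap
the platform is redesigned from scratch (boundaries recalibrated and n
re-sized at the fixed addition counts) and its maximum or expected sample
size compared with the separate-trials figure.  Both metrics are
nondecreasing in the gap, so the first crossing is found by bisection on
the integer grid and verified against its left neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .boundaries import BoundarySet
from .error_power import PowerRequest, find_n, find_n_fixed_addition
from .layout import PlatformLayout
from .outcomes import expected_N

ALPHA_MODES = ("family", "per_trial")
POWER_MODES = ("pairwise", "conjunctive")


@dataclass(frozen=True)
class SeparateTrialsSpec:
    """How K separate two-arm group-sequential trials split error and power."""

    K: int
    alpha_mode: str = "per_trial"
    power_mode: str = "pairwise"
    alpha: float = 0.025
    beta: float = 0.2
    J: int = 2
    shape: str = "triangular"
    binding: bool = True

    def __post_init__(self):
        if self.alpha_mode not in ALPHA_MODES:
            raise ValueError(f"alpha_mode must be one of {ALPHA_MODES}")
        if self.power_mode not in POWER_MODES:
            raise ValueError(f"power_mode must be one of {POWER_MODES}")

    @property
    def per_trial_alpha(self) -> float:
        if self.alpha_mode == "family":
            return 1.0 - (1.0 - self.alpha) ** (1.0 / self.K)
        return self.alpha

    @property
    def per_trial_power(self) -> float:
        if self.power_mode == "conjunctive":
            return (1.0 - self.beta) ** (1.0 / self.K)
        return 1.0 - self.beta


@dataclass(frozen=True)
class SeparateTrialsDesign:
    """K identical one-arm-vs-control designs plus combined metrics."""

    spec: SeparateTrialsSpec
    layout: PlatformLayout         # one trial (K = 1)
    bounds: BoundarySet

    @property
    def per_trial_max_N(self) -> float:
        return self.layout.max_N

    @property
    def combined_max_N(self) -> float:
        return self.spec.K * self.layout.max_N

    def combined_expected_N(self, Theta: Sequence[float]) -> float:
        """Sum of the independent trials' expectations, one effect each.

        Every trial runs to its own conclusion; there is no cross-trial
        stopping.
        """
        theta = np.asarray(Theta, dtype=float)
        if theta.size != self.spec.K:
            raise ValueError("Theta must have one effect per trial")
        return sum(expected_N(self.layout, self.bounds, [t]) for t in theta)


def design_separate(spec: SeparateTrialsSpec, theta_prime: float,
                    sigma: float = 1.0) -> SeparateTrialsDesign:
    """Design the K identical separate trials at the per-trial error/power."""
    layout, bounds = find_n(
        1, spec.J, [0.0], spec.shape, spec.per_trial_alpha,
        PowerRequest(type="pairwise", target=spec.per_trial_power),
        sigma=sigma, theta_prime=theta_prime, binding=spec.binding)
    return SeparateTrialsDesign(spec=spec, layout=layout, bounds=bounds)


@dataclass(frozen=True)
class PlatformSpec:
    """A platform design family over addition gaps: everything but n(K)."""

    K: int
    J: int
    shape: str
    alpha: float
    request: PowerRequest
    theta_prime: float
    sigma: float = 1.0
    binding: bool = True


def design_at_gap(spec: PlatformSpec, gap: float,
                  n_start: int | None = None) -> tuple:
    """Redesign the platform with arms added at equal control-count gaps.

    Arm k joins after (k - 1) * gap control patients; the boundaries are
    recalibrated and n re-sized at those fixed addition counts.
    """
    n_add = [i * gap for i in range(spec.K)]
    return find_n_fixed_addition(
        spec.K, spec.J, n_add, spec.shape, spec.alpha, spec.request,
        sigma=spec.sigma, theta_prime=spec.theta_prime, binding=spec.binding,
        n_start=n_start)


def crossover_n_add(spec: PlatformSpec, separate: SeparateTrialsDesign,
                    metric: str = "max_N", Theta: Sequence[float] | None = None,
                    paused: bool = False, gap_max: int | None = None) -> int:
    """Smallest addition gap at which the platform loses its size advantage.

    Returns the first integer gap g (control patients between successive
    arm additions) at which the platform's metric is at least the
    separate-trials metric.  ``metric`` is ``"max_N"`` or ``"expected_N"``
    (the latter requires ``Theta``).  Raises if no crossover occurs by
    ``gap_max``.
    """
    if metric not in ("max_N", "expected_N"):
        raise ValueError("metric must be 'max_N' or 'expected_N'")
    if metric == "expected_N":
        if Theta is None:
            raise ValueError("expected_N metric requires Theta")
        target = separate.combined_expected_N(Theta)
    else:
        target = separate.combined_max_N

    sizes: dict[int, int] = {}

    def platform_metric(gap: int) -> float:
        starts = [n for g, n in sizes.items() if g <= gap]
        layout, bounds = design_at_gap(spec, gap,
                                       n_start=max(starts) if starts else None)
        sizes[gap] = int(round(layout.n1))
        if metric == "max_N":
            return layout.max_N
        return expected_N(layout, bounds, Theta, paused=paused)

    if platform_metric(0) >= target:
        return 0
    if gap_max is None:
        gap_max = 3 * spec.J * sizes[0]
    if platform_metric(gap_max) < target:
        raise RuntimeError(f"no crossover found for gaps up to {gap_max}")
    lo, hi = 0, gap_max        # invariant: metric(lo) < target <= metric(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if platform_metric(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def sweep_table3(K: int, J: int, *, theta_prime: float, sigma: float = 1.0,
                 alpha_platform: float = 0.05, alpha_separate: float = 0.025,
                 beta: float = 0.2, power_type: str = "pairwise",
                 shape: str = "triangular", binding: bool = True,
                 include_crossovers: bool = False) -> dict:
    """One multi-arm sweep row: platform at a liberal familywise alpha
    versus separate trials each at the stricter per-trial alpha.

    Arms are added sequentially with an equal gap; the platform figures
    range from all arms starting at once to each arm joining only when the
    previous arm's recruitment has completed.  With ``include_crossovers``
    the minimal gaps at which the platform loses on maximum and on expected
    sample size (effect configurations: all relevant, first-only relevant,
    last-only relevant, global null) are appended.
    """
    if power_type not in POWER_MODES:
        raise ValueError(f"power_type must be one of {POWER_MODES}")
    sep_spec = SeparateTrialsSpec(K=K, alpha_mode="per_trial",
                                  power_mode=power_type, alpha=alpha_separate,
                                  beta=beta, J=J, shape=shape, binding=binding)
    separate = design_separate(sep_spec, theta_prime, sigma)

    request = PowerRequest(type=power_type, target=1.0 - beta)
    lay_lo, _ = find_n(K, J, [0.0] * K, shape, alpha_platform, request,
                       sigma=sigma, theta_prime=theta_prime, binding=binding)
    # fully staggered: each arm waits for the previous arm's full control count
    lay_hi, _ = find_n(K, J, [i * J for i in range(K)], shape, alpha_platform,
                       request, sigma=sigma, theta_prime=theta_prime,
                       binding=binding)
    row = {
        "K": K, "J": J,
        "separate_n": int(round(separate.layout.n1)),
        "separate_max_N": separate.combined_max_N,
        "platform_n_min": int(round(lay_lo.n1)),
        "platform_n_max": int(round(lay_hi.n1)),
        "platform_max_N_min": lay_lo.max_N,
        "platform_max_N_max": lay_hi.max_N,
    }
    if include_crossovers:
        spec = PlatformSpec(K=K, J=J, shape=shape, alpha=alpha_platform,
                            request=request, theta_prime=theta_prime,
                            sigma=sigma, binding=binding)
        row["crossover_max_N"] = crossover_n_add(spec, separate, "max_N")
        thp = theta_prime
        configs = {
            "Theta1": [thp] * K,
            "Theta2": [thp] + [0.0] * (K - 1),
            "Theta3": [0.0] * (K - 1) + [thp],
            "Theta4": [0.0] * K,
        }
        for name, theta in configs.items():
            row[f"crossover_E_{name}"] = crossover_n_add(
                spec, separate, "expected_N", Theta=theta)
    return row
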