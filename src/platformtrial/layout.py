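"""Trial geometry: arms, stages, staggered additions and patient counts.

A platform trial compares K experimental arms against a shared control.
Arm k is added once ``n_add[k]`` control patients have been recruited
(``n_add = 0`` for arms present from the start), runs through up to ``J_k``
analyses, and at its j-th analysis has recruited ``n_treat[k][j]`` patients
of its own while the cumulative control count stands at ``n_control[k][j]``.
Only *concurrent* controls — those recruited after the arm joined — enter
the arm's test statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence


def _as_nested_tuple(x) -> tuple:
    return tuple(tuple(float(v) for v in row) for row in x)


@dataclass(frozen=True)
class PlatformLayout:
    """Full accrual geometry of a platform trial.

    Parameters
    ----------
    K : int
        Number of experimental arms.
    J : tuple of int
        Number of analyses per arm.
    n_treat : tuple of tuple of float
        ``n_treat[k-1][j-1]`` = patients on arm k by its j-th analysis
        (cumulative, strictly increasing in j).
    n_control : tuple of tuple of float
        ``n_control[k-1][j-1]`` = total control patients recruited by arm
        k's j-th analysis (cumulative since the start of the trial).
    n_add : tuple of float
        Control patients recruited before each arm joins; 0 for arms that
        start the trial.  Nondecreasing in arm index.
    sigma : float
        Known outcome standard deviation.
    theta_prime : float
        Clinically relevant effect on the benefit scale (> 0).
    n1 : float
        First-stage size of arm 1, the scaling unit for allocation ratios.

    Counts are stored as floats so that scale-free (ratio-only) layouts can
    be used for boundary calibration; concrete designs use whole patients.
    """

    K: int
    J: tuple
    n_treat: tuple
    n_control: tuple
    n_add: tuple
    sigma: float
    theta_prime: float
    n1: float = field(default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "J", tuple(int(j) for j in self.J))
        object.__setattr__(self, "n_treat", _as_nested_tuple(self.n_treat))
        object.__setattr__(self, "n_control", _as_nested_tuple(self.n_control))
        object.__setattr__(self, "n_add", tuple(float(v) for v in self.n_add))
        if self.n1 == 0.0:
            object.__setattr__(self, "n1", self.n_treat[0][0])
        self._validate()

    def _validate(self):
        if self.K < 1:
            raise ValueError("need at least one experimental arm (K >= 1)")
        if len(self.J) != self.K or len(self.n_treat) != self.K \
                or len(self.n_control) != self.K or len(self.n_add) != self.K:
            raise ValueError("per-arm fields must all have length K")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.theta_prime <= 0:
            raise ValueError("theta_prime must be positive on the benefit scale")
        for k in range(self.K):
            if self.J[k] < 1:
                raise ValueError(f"arm {k + 1}: needs at least one stage")
            if len(self.n_treat[k]) != self.J[k] or len(self.n_control[k]) != self.J[k]:
                raise ValueError(f"arm {k + 1}: count rows must have length J_k")
            if self.n_add[k] < 0:
                raise ValueError(f"arm {k + 1}: addition count cannot be negative")
            prev_t = prev_c = 0.0
            for j in range(self.J[k]):
                nt, nc = self.n_treat[k][j], self.n_control[k][j]
                if nt <= prev_t:
                    raise ValueError(f"arm {k + 1}: treatment counts must increase with stage")
                if nc <= prev_c:
                    raise ValueError(f"arm {k + 1}: control counts must increase with stage")
                if nc - self.n_add[k] <= 0:
                    raise ValueError(f"arm {k + 1}: no concurrent controls at stage {j + 1}")
                prev_t, prev_c = nt, nc
        if any(b < a for a, b in zip(self.n_add, self.n_add[1:])):
            raise ValueError("addition counts must be nondecreasing in arm index")

    # -- derived quantities -------------------------------------------------

    @property
    def K_star(self) -> int:
        """Number of arms present at the start of the trial."""
        return sum(1 for v in self.n_add if v == 0)

    def treatment_count(self, k: int, j: int) -> float:
        """Patients on arm k (1-based) by its j-th (1-based) analysis."""
        return self.n_treat[k - 1][j - 1]

    def control_count(self, k: int, j: int) -> float:
        """Total control patients recruited by arm k's j-th analysis."""
        return self.n_control[k - 1][j - 1]

    def concurrent_controls(self, k: int, j: int) -> float:
        """Controls recruited while arm k was open, up to its j-th analysis."""
        return self.n_control[k - 1][j - 1] - self.n_add[k - 1]

    @property
    def max_N(self) -> float:
        """Maximum planned total sample size.

        Every arm runs to its final analysis, and the control is recruited
        until the last-added arm has completed, so the control contributes
        the largest of the per-arm cumulative control counts.
        """
        return total_N(self, self.J)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "J": list(self.J),
            "n_treat": [list(r) for r in self.n_treat],
            "n_control": [list(r) for r in self.n_control],
            "n_add": list(self.n_add),
            "sigma": self.sigma,
            "theta_prime": self.theta_prime,
            "n1": self.n1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlatformLayout":
        return cls(K=d["K"], J=d["J"], n_treat=d["n_treat"],
                   n_control=d["n_control"], n_add=d["n_add"],
                   sigma=d["sigma"], theta_prime=d["theta_prime"],
                   n1=d.get("n1", 0.0))


def make_standard_layout(K: int, J: int, n1: float, n_add: Sequence[float] | None = None,
                         sigma: float = 1.0, theta_prime: float = 1.0,
                         r_add: Sequence[float] | None = None) -> PlatformLayout:
    """Standard geometry: equal stages, 1:1 allocation per stage.

    Each open arm and the control recruit at the same rate, so arm k has
    ``j * n1`` patients at its j-th analysis and the same number of
    concurrent controls; the cumulative control count is
    ``n_add[k] + j * n1``.

    Addition times may be given as absolute control counts ``n_add`` or as
    ratios ``r_add`` of ``n1`` (ratio-derived counts are rounded up to
    whole patients when ``n1`` is integral).
    """
    if n1 <= 0:
        raise ValueError("n1 must be positive")
    if K < 1:
        raise ValueError("K must be at least 1")
    if (n_add is None) == (r_add is None):
        raise ValueError("give exactly one of n_add or r_add")
    if r_add is not None:
        if float(n1).is_integer():
            n_add = [math.ceil(r * n1 - 1e-9) for r in r_add]
        else:
            n_add = [r * n1 for r in r_add]
    n_add = list(n_add)
    if len(n_add) != K:
        raise ValueError("n_add must have one entry per arm")
    if any(v < 0 for v in n_add):
        raise ValueError("addition counts cannot be negative")
    n_treat = [[j * n1 for j in range(1, J + 1)] for _ in range(K)]
    n_control = [[n_add[k] + j * n1 for j in range(1, J + 1)] for k in range(K)]
    return PlatformLayout(K=K, J=[J] * K, n_treat=n_treat, n_control=n_control,
                          n_add=n_add, sigma=sigma, theta_prime=theta_prime, n1=n1)


def total_N(layout: PlatformLayout, stages) -> float:
    """Total patients recruited when arm k stops at analysis ``stages[k-1]``.

    The control keeps recruiting until, at the earliest, the last-added arm
    has had its analysis, so the control contribution is the largest
    cumulative control count among the stopping points.  The exit direction
    (futility or efficacy) does not change the count.
    """
    stages = getattr(stages, "j", stages)
    if len(stages) != layout.K:
        raise ValueError("need one stopping stage per arm")
    for k, j in enumerate(stages, start=1):
        if not 1 <= j <= layout.J[k - 1]:
            raise ValueError(f"arm {k}: invalid stopping stage {j}")
    treat = sum(layout.treatment_count(k, stages[k - 1]) for k in range(1, layout.K + 1))
    control = max(layout.control_count(k, stages[k - 1]) for k in range(1, layout.K + 1))
    return treat + control
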