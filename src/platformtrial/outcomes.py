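"""Trial outcomes: stop profiles, their probabilities and sample sizes.

A trial realisation is summarised by a stop profile: for each arm, the
analysis at which it stopped and whether it exited below the futility
bound (q = 0) or above the efficacy bound (q = 1).  The profiles partition
the sample space, each with a multivariate-normal probability Q under a
given effect vector and a total sample size N, from which the sample-size
distribution and the expected sample size follow.

Two accounting conventions for the control arm are provided.  Under
continuous recruitment the control recruits without interruption, even
during periods when no experimental arm is open.  Under paused recruitment
the control stops whenever every arm added so far has stopped and the next
arm has not yet joined; the skipped control patients are never recruited.
The paused rule here subtracts, for each inter-arm gap, the shortfall
between the next arm's join count and the largest control count reached by
the earlier arms.  Boundaries and correlations always refer to the planned
(continuous-recruitment) geometry; pausing is a sample-size accounting
change only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._regions import joint_probability
from .boundaries import BoundarySet
from .layout import PlatformLayout, total_N


@dataclass(frozen=True)
class StopProfile:
    """Per-arm stopping stage and exit direction (0 futility, 1 efficacy)."""

    j: tuple
    q: tuple

    def __post_init__(self):
        object.__setattr__(self, "j", tuple(int(v) for v in self.j))
        object.__setattr__(self, "q", tuple(int(v) for v in self.q))
        if len(self.j) != len(self.q):
            raise ValueError("stage and direction vectors must align")
        if any(v not in (0, 1) for v in self.q):
            raise ValueError("exit directions must be 0 (futility) or 1 (efficacy)")


def _validate_profile(layout: PlatformLayout, profile: StopProfile):
    if len(profile.j) != layout.K:
        raise ValueError("profile must cover every arm")
    for k, jk in enumerate(profile.j, start=1):
        if not 1 <= jk <= layout.J[k - 1]:
            raise ValueError(f"arm {k}: invalid stopping stage {jk}")


def outcome_probability(layout: PlatformLayout, bounds: BoundarySet,
                        profile: StopProfile, Theta: Sequence[float]) -> float:
    """Probability of one exact joint trial outcome under Theta.

    Each arm continues through the stages before its stopping stage and
    exits in its recorded direction; the probability is a single rectangle
    under the full cross-arm correlation.  An arm with effect ``-inf``
    stops at its first analysis for futility with probability one and is
    dropped from the integral.
    """
    _validate_profile(layout, profile)
    theta = np.asarray(Theta, dtype=float)
    if theta.size != layout.K:
        raise ValueError("Theta must have one effect per arm")
    events = []
    for k in range(1, layout.K + 1):
        if theta[k - 1] == -np.inf:
            if profile.j[k - 1] != 1 or profile.q[k - 1] != 0:
                return 0.0
            continue
        events.append((k, bounds.U[k - 1], bounds.L[k - 1],
                       profile.j[k - 1], profile.q[k - 1], theta[k - 1]))
    return joint_probability(layout, events)


def paused_N(layout: PlatformLayout, stages) -> float:
    """Total sample size under paused recruitment for given stopping stages.

    Control recruitment halts during any interval in which every arm added
    so far has already stopped and the next arm has not yet joined; the
    control patients that would have been recruited in that interval are
    subtracted from the continuous-recruitment total.
    """
    stages = getattr(stages, "j", stages)
    N = total_N(layout, stages)
    order = sorted(range(layout.K), key=lambda k: layout.n_add[k])
    for pos, k in enumerate(order):
        if layout.n_add[k] == 0:
            continue
        reached = max((layout.n_control[k2][stages[k2] - 1]
                       for k2 in order[:pos]
                       if layout.n_add[k2] < layout.n_add[k]), default=0.0)
        N -= max(0.0, layout.n_add[k] - reached)
    return N


@dataclass(frozen=True)
class OutcomeTable:
    """Every stop profile with its probability and sample sizes."""

    table: pd.DataFrame    # columns: profile, Q, N, N_paused + per-arm counts
    Theta: tuple

    @property
    def total_probability(self) -> float:
        return float(self.table["Q"].sum())

    def expected_N(self, paused: bool = False) -> float:
        col = "N_paused" if paused else "N"
        return float((self.table["Q"] * self.table[col]).sum())

    def sample_size_distribution(self, paused: bool = False) -> pd.DataFrame:
        """Probability mass function over distinct total sample sizes."""
        col = "N_paused" if paused else "N"
        pmf = self.table.groupby(col)["Q"].sum().reset_index()
        return pmf.rename(columns={col: "N", "Q": "probability"})

    def arm_sample_size_distribution(self, k: int) -> pd.DataFrame:
        """Marginal distribution of patients recruited to arm k (0 = control)."""
        col = "n_control" if k == 0 else f"n_arm{k}"
        pmf = self.table.groupby(col)["Q"].sum().reset_index()
        return pmf.rename(columns={col: "n", "Q": "probability"})


def enumerate_outcomes(layout: PlatformLayout, bounds: BoundarySet,
                       Theta: Sequence[float], max_profiles: int = 100_000) -> OutcomeTable:
    """Tabulate all stop profiles with probabilities and sample sizes.

    The enumeration has prod_k (2 J_k) rows; ``max_profiles`` guards
    against high-dimensional designs where the multivariate-normal
    integrals become impractical.
    """
    theta = np.asarray(Theta, dtype=float)
    per_arm = []
    for k in range(1, layout.K + 1):
        if theta[k - 1] == -np.inf:
            per_arm.append([(1, 0)])       # certain first-stage futility exit
        else:
            per_arm.append([(j, q) for j in range(1, layout.J[k - 1] + 1)
                            for q in (0, 1)])
    n_rows = int(np.prod([len(p) for p in per_arm]))
    if n_rows > max_profiles:
        raise RuntimeError(
            f"{n_rows} outcome profiles exceed the cap of {max_profiles}; "
            "high-dimensional enumerations are computationally impractical")
    rows = []
    for combo in itertools.product(*per_arm):
        profile = StopProfile(j=[c[0] for c in combo], q=[c[1] for c in combo])
        Q = outcome_probability(layout, bounds, profile, theta)
        row = {
            "profile": profile,
            "Q": Q,
            "N": total_N(layout, profile.j),
            "N_paused": paused_N(layout, profile.j),
            "n_control": max(layout.control_count(k, profile.j[k - 1])
                             for k in range(1, layout.K + 1)),
        }
        for k in range(1, layout.K + 1):
            row[f"n_arm{k}"] = layout.treatment_count(k, profile.j[k - 1])
        rows.append(row)
    return OutcomeTable(table=pd.DataFrame(rows), Theta=tuple(theta))


def expected_N(layout: PlatformLayout, bounds: BoundarySet,
               Theta: Sequence[float], paused: bool = False) -> float:
    """Expected total sample size: sum of Q * N over all stop profiles."""
    return enumerate_outcomes(layout, bounds, Theta).expected_N(paused=paused)


def sample_size_distribution(layout: PlatformLayout, bounds: BoundarySet,
                             Theta: Sequence[float], paused: bool = False) -> pd.DataFrame:
    """PMF of the realised total sample size under Theta."""
    return enumerate_outcomes(layout, bounds, Theta).sample_size_distribution(paused=paused)
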