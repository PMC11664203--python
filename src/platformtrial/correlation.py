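"""Joint law of the stagewise test statistics.

At arm k's j-th analysis the standardised statistic

    Z_{k,j} = (mean of arm k's outcomes - mean of its concurrent controls)
              / (sigma * sqrt(1/n_{k,j} + 1/m_{k,j}))

is computed, where m_{k,j} is the number of concurrent controls.  Under an
effect theta_k the mean of Z_{k,j} is theta_k * sqrt(I_{k,j}) with I the
Fisher information of the mean difference, and correlations across stages
and arms are driven entirely by shared patients: nested treatment samples
within an arm, and the overlap of the control windows across arms.  An arm
added after another arm's analysis window has closed shares no controls
with it and is uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .layout import PlatformLayout


def information(layout: PlatformLayout, k: int, j: int) -> float:
    """Fisher information of arm k's treatment-control difference at stage j.

    Returns ``[sigma^2 (1/n_{k,j} + 1/m_{k,j})]^{-1}`` where ``m`` counts
    concurrent controls only.  The mean of Z_{k,j} under effect theta is
    ``theta * sqrt(I_{k,j})``.
    """
    n_t = layout.treatment_count(k, j)
    m = layout.concurrent_controls(k, j)
    if m <= 0:
        raise ValueError(f"arm {k} has no concurrent controls at stage {j}")
    return 1.0 / (layout.sigma ** 2 * (1.0 / n_t + 1.0 / m))


def pairwise_correlation(layout: PlatformLayout, a: tuple, b: tuple) -> float:
    """Correlation of Z at (arm, stage) pairs ``a`` and ``b``.

    Derived from shared-patient counts: the two statistics covary through
    the treatment patients they share (nested samples, same arm only) and
    through the control patients recruited while both arms were open.
    """
    (k, j), (k2, j2) = a, b
    n_a, n_b = layout.treatment_count(k, j), layout.treatment_count(k2, j2)
    m_a, m_b = layout.concurrent_controls(k, j), layout.concurrent_controls(k2, j2)
    shared_treat = layout.treatment_count(k, min(j, j2)) if k == k2 else 0.0
    shared_ctrl = max(
        0.0,
        min(layout.control_count(k, j), layout.control_count(k2, j2))
        - max(layout.n_add[k - 1], layout.n_add[k2 - 1]),
    )
    cov_means = layout.sigma ** 2 * (shared_treat / (n_a * n_b) + shared_ctrl / (m_a * m_b))
    return cov_means * np.sqrt(information(layout, k, j) * information(layout, k2, j2))


@dataclass(frozen=True)
class JointLaw:
    """Mean shifts and correlation matrix over an ordered (arm, stage) index."""

    index: tuple
    mu: np.ndarray
    Sigma: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [f"Z[{k},{j}]" for k, j in self.index]
        return pd.DataFrame(self.Sigma, index=labels, columns=labels)


def correlation_matrix(layout: PlatformLayout, index: Sequence[tuple]) -> np.ndarray:
    """Correlation matrix of the statistics at the given (arm, stage) pairs."""
    d = len(index)
    S = np.eye(d)
    for i in range(d):
        for jj in range(i + 1, d):
            S[i, jj] = S[jj, i] = pairwise_correlation(layout, index[i], index[jj])
    return S


def default_index(layout: PlatformLayout) -> tuple:
    """Arm-major, stage-minor ordering over every (arm, stage) pair."""
    return tuple((k, j) for k in range(1, layout.K + 1)
                 for j in range(1, layout.J[k - 1] + 1))


def build_joint_law(layout: PlatformLayout, index: Sequence[tuple] | None = None,
                    Theta: Sequence[float] | None = None) -> JointLaw:
    """Joint normal law of the test statistics at the indexed analyses.

    ``index`` defaults to every (arm, stage) pair in arm-major order;
    ``Theta`` defaults to the global null (all effects zero).
    """
    idx = tuple(index) if index is not None else default_index(layout)
    theta = np.zeros(layout.K) if Theta is None else np.asarray(Theta, dtype=float)
    if theta.size != layout.K:
        raise ValueError("Theta must have one effect per arm")
    mu = np.array([theta[k - 1] * np.sqrt(information(layout, k, j)) for k, j in idx])
    return JointLaw(index=idx, mu=mu, Sigma=correlation_matrix(layout, idx))
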