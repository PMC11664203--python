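"""Deterministic multivariate-normal rectangle probabilities.

All design quantities in this package reduce to probabilities of axis-aligned
rectangles under a zero-mean multivariate normal law with a known correlation
matrix.  SciPy's ``multivariate_normal.cdf`` uses a randomised quasi-Monte
Carlo rule, so a fixed generator seed is supplied on every call: repeated
evaluations (and therefore calibrated boundaries) are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

#: absolute integration tolerance for MVN rectangle probabilities
MVN_ABSEPS = 1e-8

#: fixed seed for the randomised lattice rule, so results are reproducible
_QMC_SEED = 181612


def rectangle_probability(lower, upper, corr) -> float:
    """P(lower < Z < upper) for Z ~ N(0, corr).

    Parameters
    ----------
    lower, upper : array-like
        Rectangle limits; ``-inf`` / ``inf`` entries are allowed.
    corr : array-like
        Correlation matrix (unit diagonal, positive semidefinite).

    An empty rectangle (zero dimensions) has probability 1 by convention —
    it corresponds to intersecting no constraints.
    """
    lower = np.atleast_1d(np.asarray(lower, dtype=float))
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    d = lower.size
    if d == 0:
        return 1.0
    if upper.size != d:
        raise ValueError("lower and upper must have equal length")
    if np.any(lower >= upper):
        return 0.0
    if d == 1:
        return float(norm.cdf(upper[0]) - norm.cdf(lower[0]))
    p = multivariate_normal.cdf(
        upper,
        mean=np.zeros(d),
        cov=np.asarray(corr, dtype=float),
        lower_limit=lower,
        abseps=MVN_ABSEPS,
        releps=0.0,
        rng=np.random.default_rng(_QMC_SEED),
    )
    return float(min(max(p, 0.0), 1.0))
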