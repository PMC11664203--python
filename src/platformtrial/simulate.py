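"""Patient-level Monte Carlo oracle for any platform design.

Simulates normal outcomes patient by patient, forms every stagewise test
statistic exactly as the design defines it — arm means against the means
of concurrent controls only — applies the stopping rules, and estimates
error rates, powers and sample sizes empirically.  Serves as an
independent check of every analytic quantity in the package.

Two engines produce distributionally identical results: ``"patient"``
draws an outcome for every patient slot; ``"stagewise"`` draws the
sufficient statistics (stagewise increments of the treatment and control
sums) directly, which is much faster for large designs.  Both share the
same stream logic: one control series cut at every count the design ever
references, plus one series per arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boundaries import BoundarySet
from .layout import PlatformLayout


@dataclass
class SimResult:
    """Replicate-level outcomes of a simulated platform trial."""

    reps: int
    Theta: tuple
    seed: int
    method: str
    theta_prime: float
    reject: np.ndarray       # (reps, K) bool
    stop_stage: np.ndarray   # (reps, K) int, 1-based
    exit_dir: np.ndarray     # (reps, K) int, 0 futility / 1 efficacy
    N: np.ndarray            # (reps,) totals, continuous recruitment
    N_paused: np.ndarray     # (reps,) totals, paused recruitment

    def _rate(self, mask: np.ndarray) -> float:
        return float(np.mean(mask))

    def rate_se(self, p: float) -> float:
        return float(np.sqrt(p * (1 - p) / self.reps))

    def rejection_rate(self, arms: Sequence[int] | None = None) -> float:
        """P(at least one of the listed arms rejected); all arms by default."""
        cols = ([a - 1 for a in arms] if arms is not None
                else list(range(self.reject.shape[1])))
        if not cols:
            return 0.0
        return self._rate(self.reject[:, cols].any(axis=1))

    def fwer(self) -> float:
        """Rejection rate over the arms whose true effect is null or worse."""
        nulls = [k + 1 for k, t in enumerate(self.Theta) if t <= 0]
        return self.rejection_rate(nulls)

    def pairwise_power(self, k: int) -> float:
        return self._rate(self.reject[:, k - 1])

    def conjunctive_power(self) -> float:
        relevant = [k for k, t in enumerate(self.Theta)
                    if t >= self.theta_prime - 1e-12]
        if not relevant:
            return 1.0
        return self._rate(self.reject[:, relevant].all(axis=1))

    def disjunctive_power(self) -> float:
        return self.rejection_rate()

    def expected_N(self, paused: bool = False) -> float:
        return float(np.mean(self.N_paused if paused else self.N))

    def expected_N_se(self, paused: bool = False) -> float:
        x = self.N_paused if paused else self.N
        return float(np.std(x, ddof=1) / np.sqrt(self.reps))

    def sample_size_freqs(self, paused: bool = False) -> dict:
        vals, counts = np.unique(self.N_paused if paused else self.N,
                                 return_counts=True)
        return {float(v): c / self.reps for v, c in zip(vals, counts)}


def _control_sums(rng, layout, cuts, chunk, method):
    """Control-stream cumulative sums at the given patient counts."""
    if method == "patient":
        draws = rng.normal(0.0, layout.sigma, size=(chunk, int(cuts[-1])))
        csum = np.cumsum(draws, axis=1)
    else:
        incr = np.diff(np.concatenate([[0.0], cuts]))
        draws = rng.normal(0.0, layout.sigma * np.sqrt(incr), size=(chunk, len(cuts)))
        csum = np.cumsum(draws, axis=1)
    out = {0.0: np.zeros(chunk)}
    for i, c in enumerate(cuts):
        out[float(c)] = (csum[:, int(c) - 1] if method == "patient" else csum[:, i])
    return out


def _arm_sums(rng, layout, k, theta_k, chunk, method):
    """Arm k's cumulative outcome sums at each of its stage counts."""
    counts = np.asarray(layout.n_treat[k - 1], dtype=float)
    if method == "patient":
        draws = rng.normal(theta_k, layout.sigma, size=(chunk, int(counts[-1])))
        csum = np.cumsum(draws, axis=1)
        return csum[:, counts.astype(int) - 1]
    incr = np.diff(np.concatenate([[0.0], counts]))
    draws = rng.normal(theta_k * incr, layout.sigma * np.sqrt(incr),
                       size=(chunk, len(counts)))
    return np.cumsum(draws, axis=1)


def _decide(z: np.ndarray, U, L):
    """Apply one arm's stopping rules to its statistics (chunk, J)."""
    chunk, J = z.shape
    stage = np.zeros(chunk, dtype=int)
    exit_dir = np.zeros(chunk, dtype=int)
    active = np.ones(chunk, dtype=bool)
    for j in range(1, J + 1):
        zj = z[:, j - 1]
        up = active & (zj > U[j - 1])
        down = (active & ~up) if j == J else (active & (zj < L[j - 1]))
        stage[up | down] = j
        exit_dir[up] = 1
        exit_dir[down] = 0
        active &= ~(up | down)
    return stage, exit_dir


def simulate_trial(layout: PlatformLayout, bounds: BoundarySet,
                   Theta: Sequence[float], reps: int, seed: int,
                   method: str = "stagewise") -> SimResult:
    """Simulate the whole trial ``reps`` times under effect vector Theta.

    An arm with effect ``-inf`` is recorded as a certain first-stage
    futility stop without drawing data.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if method not in ("stagewise", "patient"):
        raise ValueError("method must be 'stagewise' or 'patient'")
    theta = np.asarray(Theta, dtype=float)
    if theta.size != layout.K:
        raise ValueError("Theta must have one effect per arm")
    rng = np.random.default_rng(seed)

    cuts = sorted({float(c) for k in range(layout.K)
                   for c in (layout.n_add[k], *layout.n_control[k]) if c > 0})
    cuts = np.asarray(cuts)

    K = layout.K
    reject = np.zeros((reps, K), dtype=bool)
    stop_stage = np.ones((reps, K), dtype=int)
    exit_dir = np.zeros((reps, K), dtype=int)

    # chunk so patient-level draws stay within a modest memory footprint
    max_stream = max(int(cuts[-1]) if cuts.size else 1,
                     max(int(r[-1]) for r in layout.n_treat))
    chunk_size = reps if method == "stagewise" else max(1, int(4_000_000 / max_stream))

    done = 0
    while done < reps:
        chunk = min(chunk_size, reps - done)
        ctrl = _control_sums(rng, layout, cuts, chunk, method)
        for k in range(1, K + 1):
            if theta[k - 1] == -np.inf:
                continue          # certain first-stage futility stop
            tsum = _arm_sums(rng, layout, k, theta[k - 1], chunk, method)
            J_k = layout.J[k - 1]
            z = np.empty((chunk, J_k))
            for j in range(1, J_k + 1):
                n_t = layout.treatment_count(k, j)
                m = layout.concurrent_controls(k, j)
                csum = ctrl[float(layout.control_count(k, j))] - ctrl[float(layout.n_add[k - 1])]
                z[:, j - 1] = ((tsum[:, j - 1] / n_t - csum / m)
                               / (layout.sigma * np.sqrt(1 / n_t + 1 / m)))
            st, ex = _decide(z, bounds.U[k - 1], bounds.L[k - 1])
            sl = slice(done, done + chunk)
            stop_stage[sl, k - 1] = st
            exit_dir[sl, k - 1] = ex
            reject[sl, k - 1] = ex == 1
        done += chunk

    # realised sample sizes from the stop profiles
    n_treat = np.array([[layout.n_treat[k][j - 1] for j in range(1, layout.J[k] + 1)]
                        + [np.nan] * (max(layout.J) - layout.J[k])
                        for k in range(K)])
    n_ctrl = np.array([[layout.n_control[k][j - 1] for j in range(1, layout.J[k] + 1)]
                       + [np.nan] * (max(layout.J) - layout.J[k])
                       for k in range(K)])
    arm_idx = np.arange(K)
    treat_tot = n_treat[arm_idx, stop_stage - 1].sum(axis=1)
    ctrl_reached = n_ctrl[arm_idx, stop_stage - 1]
    N = treat_tot + ctrl_reached.max(axis=1)

    pauses = np.zeros(reps)
    order = sorted(range(K), key=lambda k: layout.n_add[k])
    for pos, k in enumerate(order):
        if layout.n_add[k] == 0:
            continue
        earlier = [k2 for k2 in order[:pos] if layout.n_add[k2] < layout.n_add[k]]
        reached = (np.max(ctrl_reached[:, earlier], axis=1) if earlier
                   else np.zeros(reps))
        pauses += np.maximum(0.0, layout.n_add[k] - reached)
    return SimResult(reps=reps, Theta=tuple(theta), seed=seed, method=method,
                     theta_prime=layout.theta_prime, reject=reject,
                     stop_stage=stop_stage, exit_dir=exit_dir,
                     N=N, N_paused=N - pauses)
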