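"""Exact first-passage analysis of the translocation dynamics.

The Metropolis hopping dynamics on a :class:`~polytrans.pore.Landscape` is a
finite birth–death Markov chain with two absorbing states (rejection at
``x = -6``, translocation at ``x = N + 1``).  Everything the Monte Carlo
engine estimates can therefore be computed exactly: the splitting
probability, the full absorption-time distribution, the trapped mass at a
finite waiting time, and conditional first-passage moments.  This module is
the deterministic oracle used to validate the stochastic engine.

Per attempt (one Monte Carlo time step, MCT) from transient offset ``x``:

* forward hop with probability ``p_x = ½ · min(1, exp(-(E(x+1) - E(x))))``
* backward hop with probability ``q_x = ½ · min(1, exp(-(E(x-1) - E(x))))``
* stay put otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import logsumexp

from .pore import Landscape

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

LOG_HALF = math.log(0.5)


@dataclass(frozen=True)
class Chain1D:
    """Hop probabilities of the transient offsets ``x = -5 .. N``.

    ``log_p``/``log_q`` keep the forward/backward probabilities in log space
    so that products of ratios over steep landscapes never under/overflow.
    """

    log_p: np.ndarray  # log forward prob per transient state
    log_q: np.ndarray  # log backward prob per transient state
    start_index: int  # engagement state x=0 within the transient array

    @property
    def n_states(self) -> int:
        return len(self.log_p)

    @property
    def p(self) -> np.ndarray:
        return np.exp(self.log_p)

    @property
    def q(self) -> np.ndarray:
        return np.exp(self.log_q)

    @property
    def stay(self) -> np.ndarray:
        return 1.0 - self.p - self.q


def build_chain(landscape: Landscape) -> Chain1D:
    """Metropolis hop probabilities from the energy table."""
    E = landscape.energies
    # transient states are E[1:-1]; neighbours include the absorbers
    dE_fwd = E[2:] - E[1:-1]
    dE_bwd = E[:-2] - E[1:-1]
    log_p = LOG_HALF + np.minimum(0.0, -dE_fwd)
    log_q = LOG_HALF + np.minimum(0.0, -dE_bwd)
    return Chain1D(log_p, log_q, start_index=-landscape.x_reject - 1 + 0)


def splitting_probability(chain: Chain1D, start: int | None = None) -> float:
    """Probability of absorption at the translocation side before rejection.

    Uses the classical product-of-ratios solution for birth–death chains,
    evaluated in log space; the result is independent of the stay
    probabilities.
    """
    j = chain.start_index if start is None else start
    if not 0 <= j < chain.n_states:
        raise ValueError(f"start index {j} outside transient range")
    # cumulative log of pi_i = prod_{k<=i} q_k / p_k, i = 0..n-1 (pi_{-1}=1)
    log_ratio = np.concatenate([[0.0], np.cumsum(chain.log_q - chain.log_p)])
    num = logsumexp(log_ratio[: j + 1])
    den = logsumexp(log_ratio)
    return float(np.exp(num - den))


@dataclass(frozen=True)
class AbsorptionDistribution:
    """Per-step absorbed mass and survival, from a point mass at engagement."""

    translocated: np.ndarray  # mass absorbed at x=N+1 at each step t=1..t_max
    rejected: np.ndarray  # mass absorbed at x=-6 at each step
    survival: np.ndarray  # S(t) after each step

    @property
    def t(self) -> np.ndarray:
        return np.arange(1, len(self.translocated) + 1)

    @property
    def p_translocated(self) -> float:
        return float(self.translocated.sum())

    @property
    def p_rejected(self) -> float:
        return float(self.rejected.sum())


def _iterate_py(p, q, stay, start, t_max):
    n = len(p)
    v = np.zeros(n)
    v[start] = 1.0
    tr = np.zeros(t_max)
    rj = np.zeros(t_max)
    sv = np.zeros(t_max)
    for t in range(t_max):
        rj[t] = v[0] * q[0]
        tr[t] = v[-1] * p[-1]
        new = v * stay
        new[1:] += v[:-1] * p[:-1]
        new[:-1] += v[1:] * q[1:]
        v = new
        sv[t] = v.sum()
    return tr, rj, sv


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _iterate_nb(p, q, stay, start, t_max):  # pragma: no cover - numba
        n = len(p)
        v = np.zeros(n)
        v[start] = 1.0
        tr = np.zeros(t_max)
        rj = np.zeros(t_max)
        sv = np.zeros(t_max)
        new = np.zeros(n)
        for t in range(t_max):
            rj[t] = v[0] * q[0]
            tr[t] = v[n - 1] * p[n - 1]
            for j in range(n):
                acc = v[j] * stay[j]
                if j > 0:
                    acc += v[j - 1] * p[j - 1]
                if j < n - 1:
                    acc += v[j + 1] * q[j + 1]
                new[j] = acc
            v, new = new, v
            s = 0.0
            for j in range(n):
                s += v[j]
            sv[t] = s
        return tr, rj, sv


def absorption_time_distribution(
    chain: Chain1D, t_max: int, start: int | None = None
) -> AbsorptionDistribution:
    """Propagate the occupancy vector for ``t_max`` attempts.

    Exact to round-off; mass is conserved at every step (survival plus
    cumulative absorbed equals one).
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    j = chain.start_index if start is None else start
    p, q, stay = chain.p, chain.q, chain.stay
    impl = _iterate_nb if _HAVE_NUMBA else _iterate_py
    tr, rj, sv = impl(p, q, stay, j, int(t_max))
    return AbsorptionDistribution(tr, rj, sv)


@dataclass(frozen=True)
class ExactClassification:
    """Three-way outcome probabilities at waiting time ``tw`` with conditional
    translocation-time moments (NaN when no translocation mass)."""

    p_translocated: float
    p_rejected: float
    p_trapped: float
    mean_translocation_time: float
    sd_translocation_time: float
    mean_rejection_time: float
    sd_rejection_time: float
    tw: int


def _conditional_moments(mass: np.ndarray) -> tuple[float, float]:
    total = mass.sum()
    if total <= 0.0:
        return (math.nan, math.nan)
    t = np.arange(1, len(mass) + 1, dtype=float)
    m1 = float((t * mass).sum() / total)
    m2 = float((t * t * mass).sum() / total)
    var = max(m2 - m1 * m1, 0.0)
    return (m1, math.sqrt(var))


def classify_exact(landscape: Landscape, tw: int) -> ExactClassification:
    """Exact analogue of the MC translocated/rejected/trapped classification."""
    chain = build_chain(landscape)
    dist = absorption_time_distribution(chain, tw)
    p_tr = dist.p_translocated
    p_rej = dist.p_rejected
    p_trap = float(dist.survival[-1])
    mean_tr, sd_tr = _conditional_moments(dist.translocated)
    mean_rej, sd_rej = _conditional_moments(dist.rejected)
    return ExactClassification(p_tr, p_rej, p_trap, mean_tr, sd_tr, mean_rej, sd_rej, int(tw))


@dataclass(frozen=True)
class FirstPassageMoments:
    """Mean absorption times from the engagement state."""

    mean: float  # unconditional
    mean_translocated: float  # given absorption on the translocation side
    mean_rejected: float
    p_translocated: float


def mean_first_passage(chain: Chain1D, start: int | None = None) -> FirstPassageMoments:
    """Mean absorption times via the tridiagonal first-step equations.

    Solves ``(I - T) τ = 1`` for the unconditional mean and ``(I - T) u = h``
    (``h`` the per-state splitting probabilities) for the translocation-side
    restricted mean; the decomposition ``τ = P_tr·mean_tr + P_rej·mean_rej``
    holds exactly by linearity.
    """
    j = chain.start_index if start is None else start
    n = chain.n_states
    p, q, stay = chain.p, chain.q, chain.stay

    # banded (I - T)^T layout for solve_banded with T tridiagonal:
    # T[i, i+1] = p_i (hop up), T[i+1, i] = q_{i+1} (hop down), diag stay.
    ab = np.zeros((3, n))
    ab[0, 1:] = -p[:-1]  # superdiagonal of (I-T): -T[i, i+1]? see below
    ab[1, :] = 1.0 - stay
    ab[2, :-1] = -q[1:]
    # Row i of (I - T): -q_i * x_{i-1} + (1 - stay_i) * x_i - p_i * x_{i+1}
    # solve_banded stores A[i, j] at ab[1 + i - j, j]: superdiag holds -p_{j-1}?
    # A[i, i+1] = -p_i  -> ab[0, i+1] = -p_i  (as filled above)
    # A[i+1, i] = -q_{i+1} -> ab[2, i] = -q_{i+1} (as filled above)

    h = np.array([splitting_probability(chain, start=k) for k in range(n)])
    rhs = np.column_stack([np.ones(n), h])
    sol = solve_banded((1, 1), ab, rhs)
    resid = np.abs(_apply_tridiag(ab, sol) - rhs).max()
    if not np.isfinite(resid) or resid > 1e-6:
        raise np.linalg.LinAlgError(
            f"ill-conditioned first-passage solve (max residual {resid:.2e}); "
            "use absorption_time_distribution instead"
        )
    tau = sol[:, 0]
    u = sol[:, 1]
    p_tr = h[j]
    mean_tr = u[j] / p_tr if p_tr > 0 else math.nan
    p_rej = 1.0 - p_tr
    mean_rej = (tau[j] - u[j]) / p_rej if p_rej > 0 else math.nan
    return FirstPassageMoments(float(tau[j]), float(mean_tr), float(mean_rej), float(p_tr))


def _apply_tridiag(ab: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = ab.shape[1]
    y = ab[1, :, None] * x
    y[:-1] += ab[0, 1:, None] * x[1:]
    y[1:] += ab[2, :-1, None] * x[:-1]
    return y
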