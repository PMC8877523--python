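"""Drift-versus-disorder theory of polyampholyte translocation.

For long uncorrelated ±1 charge sequences threaded through a point-like pore
with translocation potential ``U`` (kBT per charge), the interplay between
the mean drive ``⟨q⟩U`` and the random-force roughness ``σ₁|U|``
(``σ₁² = 1 − ⟨q⟩²``) is captured by a single disorder parameter ``μ``
defined through ``⟨exp(−qμU)⟩ = 1``.  The translocation/rejection-time
distributions decay as ``t^−(1+μ)`` and the sojourn-time distribution as
``t^−μ``; ``μ < 1`` marks the disorder-dominated creep regime, ``1 < μ < 2``
a driven regime with anomalous fluctuations, and ``μ > 2`` ordinary drift
with a well-defined diffusivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

LOG2 = math.log(2.0)


def mu_exact(q_mean: float, U: float) -> float:
    """Disorder parameter from the exact binary-charge relation.

    For ``q = ±1`` with mean ``⟨q⟩``, the nonzero root of
    ``⟨e^(−qμU)⟩ = 1`` is ``μ = |ln((1+⟨q⟩)/(1−⟨q⟩)) / U|``; the magnitude
    is returned (only |μ| enters the predicted exponents).
    """
    if not -1 < q_mean < 1:
        raise ValueError("mean charge must lie in (-1, 1)")
    if U == 0:
        raise ValueError("potential U must be nonzero")
    if q_mean == 0:
        return 0.0
    return abs(math.log((1 + q_mean) / (1 - q_mean)) / U)


def mu_exact_root(q_mean: float, U: float) -> float:
    """Same root obtained numerically from the defining average (cross-check)."""
    if q_mean == 0:
        return 0.0
    p_plus = (1 + q_mean) / 2

    def f(mu: float) -> float:
        return p_plus * math.exp(-mu * abs(U)) + (1 - p_plus) * math.exp(mu * abs(U)) - 1

    upper = mu_exact(q_mean, U) * 2 + 1
    return brentq(f, 1e-12, upper, xtol=1e-14) if q_mean > 0 else mu_exact_root(-q_mean, U)


def mu_gaussian(q_mean: float, U: float) -> float:
    """Gaussian-statistics closed form ``μ = 2|⟨q⟩| / (|U| (1 − ⟨q⟩²))``.

    Agrees with :func:`mu_exact` to first order in ``⟨q⟩`` and bounds it from
    above for all ``0 < |⟨q⟩| < 1``.
    """
    if not -1 < q_mean < 1:
        if abs(q_mean) == 1:
            return math.inf
        raise ValueError("mean charge must lie in (-1, 1)")
    if U == 0:
        raise ValueError("potential U must be nonzero")
    return abs(2 * q_mean / (U * (1 - q_mean**2)))


def crossover_lengths(q_mean: float, U: float) -> tuple[float, float]:
    """Disorder onset length ``n_d = 1/(σ₁²U²)`` and drift crossover
    ``n_c = 1/⟨q⟩² − 1`` (infinite for a neutral sequence).

    Barriers never matter when ``n_d > n_c``: the drift overcomes the typical
    disorder barrier already at thermal scale.
    """
    var = 1 - q_mean**2
    if var <= 0 or U == 0:
        raise ValueError("need |mean charge| < 1 and U != 0")
    n_d = 1 / (var * U * U)
    n_c = math.inf if q_mean == 0 else 1 / q_mean**2 - 1
    return n_d, n_c


def barriers(n: float, q_mean: float, U: float) -> tuple[float, float]:
    """Typical disorder barrier and net barrier over ``n`` charges.

    ``E_b = √n σ₁ |U|`` is the random-walk fluctuation of the summed charge;
    the drift reduces it to ``E_B = E_b − n |⟨q⟩ U|``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sigma1 = math.sqrt(1 - q_mean**2)
    e_b = math.sqrt(n) * sigma1 * abs(U)
    return e_b, e_b - n * abs(q_mean * U)


def diblock_contribution(U: float, N: int) -> float:
    """Expected-time contribution of the symmetric diblock sequence.

    The diblock occurs with probability ``2^-N`` and faces a barrier
    ``|U|N/2`` in either direction, contributing ``exp(|U|N/2 − N ln 2)``
    monomeric diffusion times to the ensemble-average translocation time.
    """
    return math.exp(abs(U) * N / 2 - N * LOG2)


def net_charge_criterion(U: float) -> float:
    """Minimal charge fraction ``Q/N`` above which the diblock contribution
    decays exponentially with ``N``: threshold ``1 − 2 ln 2 / |U|``
    (zero when ``|U| ≤ 2 ln 2``, where the criterion is vacuous)."""
    u = abs(U)
    if u <= 2 * LOG2:
        return 0.0
    return 1 - 2 * LOG2 / u


def predicted_tail_exponent(mu: float, kind: str = "relaxation") -> float:
    """Predicted power-law exponent of the time distribution.

    ``relaxation`` (translocation/rejection times): ``−(1 + μ)``;
    ``sojourn``: ``−μ``.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if kind == "relaxation":
        return -(1 + mu)
    if kind == "sojourn":
        return -mu
    raise ValueError(f"unknown distribution kind {kind!r}")


def regime(mu: float) -> str:
    """Dynamical regime label for a disorder parameter value."""
    if mu < 1:
        return "creep"
    if mu < 2:
        return "driven-anomalous"
    return "diffusive"


@dataclass(frozen=True)
class TheoryParams:
    """Derived theory quantities for a charge density and drive."""

    q_mean: float
    U: float

    def __post_init__(self) -> None:
        if not -1 < self.q_mean < 1:
            raise ValueError("mean charge must lie in (-1, 1)")
        if self.U == 0:
            raise ValueError("potential U must be nonzero")

    @classmethod
    def from_net_charge(cls, Q: float, N: int, U: float) -> "TheoryParams":
        return cls(Q / N, U)

    @property
    def sigma1_sq(self) -> float:
        return 1 - self.q_mean**2

    @property
    def mu(self) -> float:
        return mu_exact(self.q_mean, self.U)

    @property
    def mu_gaussian(self) -> float:
        return mu_gaussian(self.q_mean, self.U)

    @property
    def mu_scaling_ratio(self) -> float:
        """Diagnostic ``n_d/n_c`` ratio; equals ``(μ_gaussian/2)²``."""
        n_d, n_c = crossover_lengths(self.q_mean, self.U)
        return 0.0 if math.isinf(n_c) else n_d / n_c

    @property
    def crossovers(self) -> tuple[float, float]:
        return crossover_lengths(self.q_mean, self.U)

    @property
    def drift_dominates(self) -> bool:
        n_d, n_c = self.crossovers
        return n_d > n_c

    @property
    def regime(self) -> str:
        return regime(self.mu)

    @property
    def tail_exponent(self) -> float:
        return predicted_tail_exponent(self.mu)

    def summary(self) -> dict:
        n_d, n_c = self.crossovers
        return {
            "q_mean": self.q_mean,
            "U": self.U,
            "sigma1_sq": self.sigma1_sq,
            "mu_exact": self.mu,
            "mu_gaussian": self.mu_gaussian,
            "n_d": n_d,
            "n_c": n_c,
            "drift_dominates": self.drift_dominates,
            "regime": self.regime,
            "relaxation_tail_exponent": self.tail_exponent,
            "sojourn_tail_exponent": predicted_tail_exponent(self.mu, "sojourn"),
        }
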