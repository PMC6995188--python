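"""Design inputs and the multivariate-normal law of the Wald statistics.

A fixed-sample multi-arm trial compares K experimental arms to a shared
control.  Hypotheses are one-sided, H_k: tau_k <= 0, tested through Wald
statistics z_k = tauhat_k * sqrt(I_k), where I_k is the information level
of the arm-k contrast.  Jointly, (Z_1, ..., Z_K) is (asymptotically)
multivariate normal with unit variances and correlations induced solely by
the common control arm, which gives the one-factor covariance exploited by
:mod:`polyarm.mvnorm`.

Supported outcome families:

* normal with known per-arm standard deviations: I_k = 1 / (sigma_0^2/n_0
  + sigma_k^2/n_k); the arm means play no role, only contrasts matter;
* Bernoulli with control response rate pi_0: I_k = 1 / (pi_0(1-pi_0)/n_0
  + pi_k(1-pi_k)/n_k), evaluated at the response rates assumed by the
  effect scenario (the analysis-stage plug-in with estimated rates lives
  in the simulator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from . import mvnorm

__all__ = [
    "MAX_ARMS",
    "MCCS",
    "POWER_TYPES",
    "NormalOutcome",
    "BernoulliOutcome",
    "DesignSpec",
    "Design",
    "EffectScenario",
    "information",
    "z_loadings",
    "z_distribution",
    "p_values",
]

MAX_ARMS = 5

MCCS = (
    "none",
    "bonferroni",
    "sidak",
    "dunnett",
    "holm_bonferroni",
    "holm_sidak",
    "stepdown_dunnett",
    "hochberg",
    "benjamini_hochberg",
    "benjamini_yekutieli",
)

POWER_TYPES = ("conjunctive", "disjunctive", "marginal")

ALLOCATIONS = ("explicit", "A_optimal", "D_optimal", "E_optimal")


class InvalidDesignError(ValueError):
    """Raised when design inputs violate a validity constraint."""


@dataclass(frozen=True)
class NormalOutcome:
    """Normally distributed outcomes with known standard deviations.

    Parameters
    ----------
    sigmas : sequence of float
        Standard deviations (sigma_0, ..., sigma_K), control first.
    """

    sigmas: tuple

    family = "normal"

    def __post_init__(self):
        object.__setattr__(self, "sigmas", tuple(float(s) for s in self.sigmas))
        if any(s <= 0 for s in self.sigmas):
            raise InvalidDesignError("all standard deviations must be positive")

    @property
    def K(self) -> int:
        return len(self.sigmas) - 1

    def variances(self, scenario: "EffectScenario | None" = None) -> np.ndarray:
        return np.asarray(self.sigmas, dtype=float) ** 2


@dataclass(frozen=True)
class BernoulliOutcome:
    """Bernoulli outcomes (response rates), with control rate pi_0."""

    pi0: float

    family = "bernoulli"

    def __post_init__(self):
        if not 0.0 < self.pi0 < 1.0:
            raise InvalidDesignError("pi0 must lie in (0, 1)")

    def variances(self, scenario: "EffectScenario") -> np.ndarray:
        if scenario.pis is None:
            raise InvalidDesignError("Bernoulli scenarios must carry response rates")
        pis = np.asarray(scenario.pis, dtype=float)
        if np.any((pis <= 0.0) | (pis >= 1.0)):
            raise InvalidDesignError("response rates must lie strictly in (0, 1)")
        return pis * (1.0 - pis)


@dataclass(frozen=True)
class Design:
    """Resolved per-arm sample sizes: n_k = r_k * n_0."""

    n0: float
    ratios: tuple

    def __post_init__(self):
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        if self.n0 <= 0 or any(r <= 0 for r in self.ratios):
            raise InvalidDesignError("sample sizes and ratios must be positive")

    @property
    def K(self) -> int:
        return len(self.ratios)

    @property
    def n(self) -> np.ndarray:
        """Experimental-arm sizes (n_1, ..., n_K)."""
        return self.n0 * np.asarray(self.ratios)

    @property
    def total(self) -> float:
        return self.n0 + float(self.n.sum())

    def rounded_up(self) -> "Design":
        """Integer design: every arm size rounded up (ceiling)."""
        n0 = math.ceil(self.n0 - 1e-9)
        n = [math.ceil(v - 1e-9) for v in self.n]
        return Design(n0=n0, ratios=tuple(v / n0 for v in n))


@dataclass(frozen=True)
class EffectScenario:
    """A configuration of true treatment effects.

    For Bernoulli outcomes the scenario is defined directly by the
    response rates ``pis = (pi_0, pi_1, ..., pi_K)`` and
    tau_k = pi_k - pi_0; for normal outcomes by ``tau`` alone.
    """

    label: str
    tau: tuple
    pis: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "tau", tuple(float(t) for t in self.tau))
        if self.pis is not None:
            pis = tuple(float(p) for p in self.pis)
            object.__setattr__(self, "pis", pis)
            tau = np.asarray(pis[1:]) - pis[0]
            if not np.allclose(tau, self.tau, atol=1e-12):
                raise InvalidDesignError("tau inconsistent with response rates")

    @property
    def K(self) -> int:
        return len(self.tau)

    @staticmethod
    def _build(label, taus, pi0=None):
        if pi0 is None:
            return EffectScenario(label, tuple(taus))
        pis = (pi0,) + tuple(pi0 + t for t in taus)
        return EffectScenario(label, tuple(taus), pis)

    @classmethod
    def global_null(cls, K: int, pi0: float | None = None) -> "EffectScenario":
        return cls._build("H_G", (0.0,) * K, pi0)

    @classmethod
    def global_alternative(cls, K: int, delta1: float,
                           pi0: float | None = None) -> "EffectScenario":
        return cls._build("H_A", (delta1,) * K, pi0)

    @classmethod
    def lfc(cls, K: int, k: int, delta1: float, delta0: float,
            pi0: float | None = None) -> "EffectScenario":
        """Least favourable configuration for arm k (1-based)."""
        if not 1 <= k <= K:
            raise InvalidDesignError("LFC arm index out of range")
        taus = [delta0] * K
        taus[k - 1] = delta1
        return cls._build(f"LFC_{k}", tuple(taus), pi0)

    @classmethod
    def custom(cls, taus, pi0: float | None = None,
               label: str = "custom") -> "EffectScenario":
        return cls._build(label, tuple(taus), pi0)


@dataclass(frozen=True)
class DesignSpec:
    """All user inputs defining a multi-arm design problem."""

    K: int
    alpha: float
    beta: float
    delta1: float
    delta0: float
    mcc: str
    power_type: str
    outcome: NormalOutcome | BernoulliOutcome
    allocation: str = "explicit"
    ratios: tuple | None = None
    assumed_pis: tuple | None = None
    integer_n: bool = False
    plots: bool = False
    quality: str = "medium"

    def __post_init__(self):
        if not 1 <= self.K <= MAX_ARMS:
            raise InvalidDesignError(f"K must lie in 1..{MAX_ARMS}")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidDesignError("alpha must lie in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise InvalidDesignError("beta must lie in (0, 1)")
        if 1.0 - self.beta <= self.alpha:
            raise InvalidDesignError("target power 1-beta must exceed alpha")
        if self.delta1 <= 0:
            raise InvalidDesignError("delta1 must be positive")
        if self.delta0 >= self.delta1:
            raise InvalidDesignError("delta0 must be smaller than delta1")
        if self.mcc not in MCCS:
            raise InvalidDesignError(f"unknown correction {self.mcc!r}")
        if self.power_type not in POWER_TYPES:
            raise InvalidDesignError(f"unknown power type {self.power_type!r}")
        if self.allocation not in ALLOCATIONS:
            raise InvalidDesignError(f"unknown allocation rule {self.allocation!r}")
        if self.outcome.family == "normal":
            if self.outcome.K != self.K:
                raise InvalidDesignError("need K+1 standard deviations")
        else:
            pi0 = self.outcome.pi0
            if not 0.0 < self.delta1 < 1.0 - pi0:
                raise InvalidDesignError(
                    "Bernoulli outcomes need delta1 in (0, 1-pi0)")
            if not -pi0 < self.delta0:
                raise InvalidDesignError("Bernoulli outcomes need delta0 > -pi0")
        if self.allocation == "explicit":
            ratios = self.ratios if self.ratios is not None else (1.0,) * self.K
            ratios = tuple(float(r) for r in ratios)
            if len(ratios) != self.K or any(r <= 0 for r in ratios):
                raise InvalidDesignError("need K positive allocation ratios")
            object.__setattr__(self, "ratios", ratios)
        if self.assumed_pis is not None:
            object.__setattr__(
                self, "assumed_pis",
                tuple(float(p) for p in self.assumed_pis))

    # -- scenario builders ------------------------------------------------
    def _pi0(self):
        return self.outcome.pi0 if self.outcome.family == "bernoulli" else None

    def scenario(self, label: str) -> EffectScenario:
        """Build a named scenario: 'H_G', 'H_A' or 'LFC_k'."""
        if label == "H_G":
            return EffectScenario.global_null(self.K, self._pi0())
        if label == "H_A":
            return EffectScenario.global_alternative(self.K, self.delta1, self._pi0())
        if label.startswith("LFC_"):
            k = int(label.split("_")[1])
            return EffectScenario.lfc(self.K, k, self.delta1, self.delta0, self._pi0())
        raise InvalidDesignError(f"unknown scenario label {label!r}")

    def standard_scenarios(self) -> list[EffectScenario]:
        labels = ["H_G", "H_A"] + [f"LFC_{k}" for k in range(1, self.K + 1)]
        return [self.scenario(lab) for lab in labels]


# -- the MVN law of the Wald statistics -----------------------------------

def information(design: Design, model, scenario: EffectScenario) -> np.ndarray:
    """Information levels I_k of the K treatment-vs-control contrasts."""
    v = model.variances(scenario)
    n = design.n
    return 1.0 / (v[0] / design.n0 + v[1:] / n)


def z_loadings(design: Design, model, scenario: EffectScenario):
    """Mean vector and one-factor loadings of (Z_1, ..., Z_K).

    Returns ``(eta, c)`` with eta_l = tau_l * sqrt(I_l) and
    c_l = sqrt(I_l * v_0 / n_0), so that Cov(Z_i, Z_j) = c_i c_j.
    """
    v = model.variances(scenario)
    info = information(design, model, scenario)
    tau = np.asarray(scenario.tau, dtype=float)
    eta = tau * np.sqrt(info)
    c = np.sqrt(info * (v[0] / design.n0))
    return eta, c


def z_distribution(design: Design, model, scenario: EffectScenario):
    """Mean vector and covariance matrix of the Wald statistics."""
    eta, c = z_loadings(design, model, scenario)
    return eta, mvnorm.cov_from_loadings(c)


def p_values(z) -> np.ndarray:
    """One-sided p-values p_k = 1 - Phi(z_k)."""
    return ndtr(-np.asarray(z, dtype=float))


def null_covariance(spec: DesignSpec, ratios) -> np.ndarray:
    """Covariance of Z under the global null, as used to calibrate
    Dunnett-type thresholds.  Depends on the allocation ratios only."""
    design = Design(n0=1.0, ratios=tuple(ratios))
    _, cov = z_distribution(design, spec.outcome, spec.scenario("H_G"))
    return cov
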