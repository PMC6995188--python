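"""Optimal allocation ratios by A-, D- and E-optimality.

The criterion is evaluated at total sample size normalised to one
(n_0 = 1/(1 + sum r_k), n_k = r_k n_0), the standard fixed-total
convention.  The information matrix is the inverse of the covariance of
the treatment-effect estimates,

    Cov(tauhat)_kk   = v_0/n_0 + v_k/n_k,
    Cov(tauhat)_k1k2 = v_0/n_0           (k1 != k2),

with v_k the outcome variance of arm k (sigma_k^2 for normal outcomes,
pi_k(1-pi_k) at the assumed response rates for Bernoulli outcomes).

A-optimality has the closed form r_k = sqrt(v_k / (K v_0)) (which gives
Neyman allocation r_1 = sigma_1/sigma_0 at K = 1 and the classic
1/sqrt(K) control weighting for equal variances); D- and E-optimal
ratios are found by numerical optimisation over log-ratios with multiple
restarts, and the A-optimal closed form is polished the same way as a
guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["AllocationProblem", "tau_covariance", "criterion_value",
           "optimal_ratios", "resolve_allocation"]


@dataclass(frozen=True)
class AllocationProblem:
    """An A/D/E-optimal allocation problem.

    ``variances`` holds (v_0, v_1, ..., v_K), control first.
    """

    criterion: str
    variances: tuple

    def __post_init__(self):
        if self.criterion not in ("A", "D", "E"):
            raise ValueError("criterion must be 'A', 'D' or 'E'")
        v = np.asarray(self.variances, dtype=float)
        if np.any(v <= 0):
            raise ValueError("variances must be positive")
        object.__setattr__(self, "variances", tuple(float(x) for x in v))

    @property
    def K(self) -> int:
        return len(self.variances) - 1


def tau_covariance(ratios, variances) -> np.ndarray:
    """Covariance of the treatment-effect estimates at unit total size."""
    r = np.asarray(ratios, dtype=float)
    v = np.asarray(variances, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    n0 = 1.0 / (1.0 + r.sum())
    nk = r * n0
    cov = np.full((len(r), len(r)), v[0] / n0)
    cov[np.diag_indices(len(r))] += v[1:] / nk
    return cov


def criterion_value(criterion: str, ratios, variances) -> float:
    """Value to be minimised (A: trace, D: log det, E: largest eigenvalue
    of the covariance — minimising these is equivalent to the stated
    criteria on the information matrix)."""
    cov = tau_covariance(ratios, variances)
    if criterion == "A":
        return float(np.trace(cov))
    if criterion == "D":
        return float(np.linalg.slogdet(cov)[1])
    return float(np.linalg.eigvalsh(cov)[-1])


def _numeric_optimum(criterion, variances, starts):
    best = None
    for x0 in starts:
        res = minimize(
            lambda x: criterion_value(criterion, np.exp(x), variances),
            np.log(np.asarray(x0, dtype=float)), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise ArithmeticError("allocation optimiser failed to converge")
    return np.exp(best.x)


def optimal_ratios(problem: AllocationProblem) -> np.ndarray:
    """Allocation ratios optimising the requested criterion."""
    v = np.asarray(problem.variances)
    K = problem.K
    closed_a = np.sqrt(v[1:] / (K * v[0]))
    starts = [np.ones(K), closed_a, np.full(K, 0.5), np.full(K, 2.0)]
    if problem.criterion == "A":
        # closed form; polish numerically as a safeguard
        num = _numeric_optimum("A", v, [closed_a])
        if np.max(np.abs(num - closed_a) / closed_a) > 1e-3:  # pragma: no cover
            return num
        return closed_a
    return _numeric_optimum(problem.criterion, v, starts)


def resolve_allocation(spec) -> tuple:
    """Resolve the allocation ratios of a design specification."""
    if spec.allocation == "explicit":
        return tuple(spec.ratios)
    criterion = spec.allocation.split("_")[0]
    if spec.outcome.family == "normal":
        variances = np.asarray(spec.outcome.sigmas) ** 2
    else:
        pis = spec.assumed_pis
        if pis is None:
            # default: control at pi0, experimental arms at pi0 + delta1
            pis = (spec.outcome.pi0,) + (spec.outcome.pi0 + spec.delta1,) * spec.K
        pis = np.asarray(pis, dtype=float)
        if len(pis) != spec.K + 1 or np.any((pis <= 0) | (pis >= 1)):
            raise ValueError("assumed response rates must be K+1 values in (0, 1)")
        variances = pis * (1.0 - pis)
    problem = AllocationProblem(criterion, tuple(variances))
    return tuple(optimal_ratios(problem))
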