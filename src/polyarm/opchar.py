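"""Exact operating characteristics of a design x scenario x correction.

The primitive is the rejection-set distribution: the probability of each
of the 2^K possible sets of rejected hypotheses under the MVN law of the
Wald statistics.  Single-step corrections give 2^K rectangle
probabilities.  Step-wise corrections are handled exactly (K <= 3) by
partitioning on the K! orderings of the statistics: each (ordering,
stop-index) cell is a staircase region integrated by
:func:`polyarm.mvnorm.nested_chain_prob`.  For K in {4, 5} a deterministic
scrambled-Sobol quasi-Monte-Carlo integration of the rejection rule is
used instead (fixed scrambling seed, 2^18 points).

All eleven operating characteristics are exact expectations over the
rejection-set distribution.  A hypothesis H_k counts as a true null iff
tau_k <= 0 (the one-sided hypotheses are H_k: tau_k <= 0, so the boundary
belongs to the null).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

from . import mvnorm
from .corrections import CorrectionThresholds, apply_correction_matrix
from .model import (Design, EffectScenario, MAX_ARMS, InvalidDesignError,
                    z_loadings)

__all__ = [
    "RejectionDistribution",
    "OpChar",
    "rejection_distribution",
    "operating_characteristics",
    "opchar_table",
    "opchar_curve",
]

_QMC_POINTS = 2 ** 18
_QMC_SEED = 20200131  # fixed scrambling seed: results are deterministic


@dataclass(frozen=True)
class RejectionDistribution:
    """Probability of each rejection set S, S a subset of {1, ..., K}.

    Subsets are keyed by frozensets of 1-based arm indices.  Entries are
    clipped at zero and the total is renormalised provided it is within
    1e-6 of one; a larger drift raises an integration error.
    """

    probs: dict
    K: int

    @classmethod
    def from_raw(cls, probs: dict, K: int) -> "RejectionDistribution":
        clipped = {s: max(float(p), 0.0) for s, p in probs.items()}
        total = sum(clipped.values())
        if abs(total - 1.0) > 1e-6:
            raise ArithmeticError(
                f"rejection-set probabilities sum to {total:.8f}; "
                "MVN integration failed")
        return cls({s: p / total for s, p in clipped.items()}, K)

    @property
    def total(self) -> float:
        return sum(self.probs.values())

    def prob_reject(self, k: int) -> float:
        """Marginal probability that H_k is rejected (k is 1-based)."""
        return sum(p for s, p in self.probs.items() if k in s)


def _single_step_distribution(eta, c, gamma):
    K = len(eta)
    zc = ndtri(1.0 - gamma)
    subsets = list(itertools.chain.from_iterable(
        itertools.combinations(range(1, K + 1), r) for r in range(K + 1)))
    lower = np.full((len(subsets), K), -np.inf)
    upper = np.full((len(subsets), K), np.inf)
    for i, s in enumerate(subsets):
        for k in range(1, K + 1):
            if k in s:
                lower[i, k - 1] = zc
            else:
                upper[i, k - 1] = zc
    probs = mvnorm.rect_probs(eta, c, lower, upper)
    return {frozenset(s): float(p) for s, p in zip(subsets, probs)}


def _stepwise_cells(K: int, m: int, zs: np.ndarray, family: str):
    """Limit chain for the (ordering, m-rejections) cell.

    Rank r (1-based) holds the r-th largest statistic; zs[r-1] is its
    critical value (non-increasing in r).  Returns the processing order
    of ranks and their (lo, hi) limits, ``None`` meaning 'previous
    level's variable'.  The monotone threshold structure guarantees the
    limits never cross, keeping every integrand smooth.
    """
    inf = np.inf
    if family == "step_down":
        ranks = list(range(1, K + 1))  # outermost rank 1
        limits = []
        for r in ranks:
            if r <= m:
                limits.append((zs[r - 1], inf if r == 1 else None))
            elif r == m + 1:
                limits.append((-inf, zs[r - 1]))
            else:
                limits.append((-inf, None))
        return ranks, limits
    # step_up: outermost rank K
    ranks = list(range(K, 0, -1))
    limits = []
    for r in ranks:
        if r > m:
            limits.append((None if r < K else -inf, zs[r - 1]))
        elif r == m:
            limits.append((zs[r - 1], inf))
        else:
            limits.append((None, inf))
    return ranks, limits


def _stepwise_distribution_exact(eta, c, thr: CorrectionThresholds):
    K = len(eta)
    zs = thr.z_critical
    probs: dict = {}
    for perm in itertools.permutations(range(K)):
        # perm[r-1] is the 0-based arm occupying rank r
        for m in range(K + 1):
            ranks, limits = _stepwise_cells(K, m, zs, thr.family)
            seq = [perm[r - 1] for r in ranks]
            p = mvnorm.nested_chain_prob(eta, c, seq, limits)
            key = frozenset(perm[i] + 1 for i in range(m))
            probs[key] = probs.get(key, 0.0) + p
    return probs


def _stepwise_distribution_qmc(eta, c, thr: CorrectionThresholds):
    K = len(eta)
    sob = qmc.Sobol(d=K + 1, scramble=True, seed=_QMC_SEED)
    u = sob.random(_QMC_POINTS)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    shocks = ndtri(u)
    s = np.sqrt(1.0 - c * c)
    z = eta + np.outer(shocks[:, 0], c) + shocks[:, 1:] * s
    rej = apply_correction_matrix(ndtr(-z), thr)
    codes = rej @ (1 << np.arange(K))
    counts = np.bincount(codes, minlength=1 << K)
    probs = {}
    for code, cnt in enumerate(counts):
        key = frozenset(k + 1 for k in range(K) if code >> k & 1)
        probs[key] = cnt / len(codes)
    return probs


def rejection_distribution(design: Design, model, scenario: EffectScenario,
                           thr: CorrectionThresholds) -> RejectionDistribution:
    """Distribution of the set of rejected hypotheses."""
    eta, c = z_loadings(design, model, scenario)
    K = len(eta)
    if K > MAX_ARMS:
        raise InvalidDesignError(f"K is capped at {MAX_ARMS}")
    if K != thr.K:
        raise InvalidDesignError("thresholds dimension does not match design")
    if thr.family == "single_step":
        probs = _single_step_distribution(eta, c, thr.gammas[0])
    elif K <= 3:
        probs = _stepwise_distribution_exact(eta, c, thr)
    else:
        warnings.warn(
            "step-wise corrections with K >= 4 use quasi-Monte-Carlo "
            "integration; expect a longer runtime", RuntimeWarning)
        probs = _stepwise_distribution_qmc(eta, c, thr)
    return RejectionDistribution.from_raw(probs, K)


@dataclass(frozen=True)
class OpChar:
    """The eleven operating characteristics of one design/scenario/MCC."""

    p_con: float
    p_dis: float
    p_marginal: tuple
    pher: float
    fwer_i: tuple
    fwer_ii: tuple
    fdr: float
    fndr: float
    pfdr: float
    sensitivity: float
    specificity: float

    @property
    def K(self) -> int:
        return len(self.p_marginal)

    def as_series(self, prefix: str = "") -> pd.Series:
        d = {"P_con": self.p_con, "P_dis": self.p_dis}
        for k, p in enumerate(self.p_marginal, 1):
            d[f"P_{k}"] = p
        d["PHER"] = self.pher
        for a, p in enumerate(self.fwer_i, 1):
            d[f"FWER_I{a}"] = p
        for a, p in enumerate(self.fwer_ii, 1):
            d[f"FWER_II{a}"] = p
        d.update(FDR=self.fdr, FNDR=self.fndr, pFDR=self.pfdr,
                 Sensitivity=self.sensitivity, Specificity=self.specificity)
        return pd.Series({prefix + k: v for k, v in d.items()})


def opchar_from_distribution(dist: RejectionDistribution,
                             tau) -> OpChar:
    """Exact expectations of all eleven quantities over the rejection law."""
    K = dist.K
    tau = np.asarray(tau, dtype=float)
    false_nulls = set(np.flatnonzero(tau > 0) + 1)
    true_nulls = set(range(1, K + 1)) - false_nulls

    p_con = p_dis = pher = fdr = fndr = 0.0
    e_correct_rej = e_correct_not = 0.0
    p_any = 0.0
    fwer_i = np.zeros(K)
    fwer_ii = np.zeros(K)
    p_marginal = np.zeros(K)
    for s, p in dist.probs.items():
        R = len(s)
        V = len(s & true_nulls)
        T = len(false_nulls - s)
        if R == K:
            p_con += p
        if R > 0:
            p_dis += p
            p_any += p
        for k in s:
            p_marginal[k - 1] += p
        pher += p * V / K
        if V >= 1:
            fwer_i[:V] += p
        if T >= 1:
            fwer_ii[:T] += p
        fdr += p * (V / max(R, 1))
        fndr += p * (T / max(K - R, 1))
        e_correct_rej += p * (R - V)
        e_correct_not += p * (len(true_nulls) - V)
    pfdr = fdr / p_any if p_any > 1e-12 else float("nan")
    sens = (e_correct_rej / len(false_nulls)) if false_nulls else float("nan")
    spec = (e_correct_not / len(true_nulls)) if true_nulls else float("nan")
    return OpChar(
        p_con=p_con, p_dis=p_dis, p_marginal=tuple(p_marginal), pher=pher,
        fwer_i=tuple(fwer_i), fwer_ii=tuple(fwer_ii), fdr=fdr, fndr=fndr,
        pfdr=pfdr, sensitivity=sens, specificity=spec)


def operating_characteristics(design: Design, model,
                              scenario: EffectScenario,
                              thr: CorrectionThresholds) -> OpChar:
    dist = rejection_distribution(design, model, scenario, thr)
    return opchar_from_distribution(dist, scenario.tau)


def opchar_table(design: Design, model, scenarios,
                 thr: CorrectionThresholds) -> pd.DataFrame:
    """One row of operating characteristics per scenario."""
    rows = {}
    for sc in scenarios:
        oc = operating_characteristics(design, model, sc, thr)
        rows[sc.label] = oc.as_series()
    df = pd.DataFrame(rows).T
    df.index.name = "scenario"
    return df


def opchar_curve(design: Design, model, spec, thr: CorrectionThresholds,
                 theta_grid, mode: str = "shifted_all") -> pd.DataFrame:
    """Operating characteristics along a grid of effect sizes theta.

    ``shifted_all`` sets tau_1 = ... = tau_K = theta (so theta=0
    reproduces H_G and theta=delta1 reproduces H_A); ``shifted_one``
    sets tau_k = theta and tau_l = theta - (delta1 - delta0) for l != k
    (theta=delta1 reproduces LFC_k), reporting the marginal powers P_k.
    """
    if mode not in ("shifted_all", "shifted_one"):
        raise ValueError("mode must be 'shifted_all' or 'shifted_one'")
    pi0 = spec.outcome.pi0 if spec.outcome.family == "bernoulli" else None
    rows = []
    for theta in np.asarray(theta_grid, dtype=float):
        if mode == "shifted_all":
            taus = [theta] * spec.K
            if pi0 is not None:
                _check_theta_pis(pi0, taus)
            sc = EffectScenario.custom(taus, pi0, label=f"theta={theta:g}")
            oc = operating_characteristics(design, model, sc, thr)
            rows.append(pd.concat([pd.Series({"theta": theta}), oc.as_series()]))
        else:
            gap = spec.delta1 - spec.delta0
            vals = {"theta": theta}
            for k in range(1, spec.K + 1):
                taus = [theta - gap] * spec.K
                taus[k - 1] = theta
                if pi0 is not None:
                    _check_theta_pis(pi0, taus)
                sc = EffectScenario.custom(taus, pi0, label=f"P_{k}")
                oc = operating_characteristics(design, model, sc, thr)
                vals[f"P_{k}"] = oc.p_marginal[k - 1]
            rows.append(pd.Series(vals))
    return pd.DataFrame(rows).reset_index(drop=True)


def _check_theta_pis(pi0, taus):
    pis = pi0 + np.asarray(taus)
    if np.any((pis <= 0.0) | (pis >= 1.0)):
        raise InvalidDesignError(
            "theta grid pushes a response rate outside (0, 1)")
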