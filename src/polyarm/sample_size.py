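"""Sample-size determination by one-dimensional root solving on n_0.

With the allocation ratios fixed, every power quantity is monotone
increasing in the control-arm size n_0, so the smallest n_0 attaining the
target 1 - beta is found by geometric bracketing followed by Brent's
method.  Three power types are supported: the conjunctive and disjunctive
power under the global alternative H_A, and the minimum marginal power
over the least favourable configurations LFC_k.  If integer sample sizes
are requested the continuous solution is rounded up arm-wise, so the
integer design's power is at least the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import allocation as _allocation
from .corrections import CorrectionThresholds, thresholds
from .model import Design, DesignSpec, InvalidDesignError, null_covariance
from .opchar import operating_characteristics, rejection_distribution

__all__ = ["PowerRequirement", "power_at", "required_sample_size",
           "SampleSizeResult"]

_N0_CAP = 1e7


@dataclass(frozen=True)
class PowerRequirement:
    power_type: str
    target: float

    def __post_init__(self):
        if self.power_type not in ("conjunctive", "disjunctive", "marginal"):
            raise InvalidDesignError(f"unknown power type {self.power_type!r}")
        if not 0.0 < self.target < 1.0:
            raise InvalidDesignError("target power must lie in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    """A solved design with its achieved power.

    ``design`` is the continuous solution; ``integer_design`` is the
    ceiling-rounded version (None unless requested).  Achieved powers are
    reported for both, evaluated by exact MVN integration.
    """

    design: Design
    thresholds: CorrectionThresholds
    power_type: str
    target: float
    achieved_power: float
    integer_design: Design | None = None
    achieved_power_integer: float | None = None

    @property
    def final_design(self) -> Design:
        return self.integer_design if self.integer_design is not None else self.design


def power_at(n0: float, spec: DesignSpec, ratios, thr: CorrectionThresholds) -> float:
    """The controlled power of the design with control-arm size n0."""
    if n0 <= 0:
        raise InvalidDesignError("n0 must be positive")
    design = Design(n0=float(n0), ratios=tuple(ratios))
    if spec.power_type == "marginal":
        vals = []
        for k in range(1, spec.K + 1):
            dist = rejection_distribution(
                design, spec.outcome, spec.scenario(f"LFC_{k}"), thr)
            vals.append(dist.prob_reject(k))
        return float(min(vals))
    oc = operating_characteristics(
        design, spec.outcome, spec.scenario("H_A"), thr)
    return oc.p_con if spec.power_type == "conjunctive" else oc.p_dis


def required_sample_size(spec: DesignSpec,
                         requirement: PowerRequirement | None = None,
                         ratios=None) -> SampleSizeResult:
    """Smallest n_0 (continuous) meeting the power requirement.

    Allocation ratios are resolved first (explicitly or by A/D/E
    optimality); Dunnett-type thresholds are calibrated to the
    global-null covariance, which depends on the ratios only.
    """
    if requirement is None:
        requirement = PowerRequirement(spec.power_type, 1.0 - spec.beta)
    if requirement.power_type != spec.power_type:
        spec = DesignSpec(**{**spec.__dict__, "power_type": requirement.power_type})
    if ratios is None:
        ratios = _allocation.resolve_allocation(spec)
    thr = thresholds(spec.mcc, spec.alpha, spec.K,
                     covariance=null_covariance(spec, ratios))
    target = requirement.target

    lo, hi = None, 1.0
    p_prev = -np.inf
    while hi <= _N0_CAP:
        p = power_at(hi, spec, ratios, thr)
        if p < p_prev - 1e-9:
            raise ArithmeticError(
                "power is not monotone in n0; bracketing failed")
        p_prev = p
        if p >= target:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise ArithmeticError(
            f"target power {target} unattainable with n0 <= {_N0_CAP:g}")

    if lo is None:
        lo = 1e-6  # target already met at n0 = 1; the root lies below
    n0 = brentq(lambda x: power_at(x, spec, ratios, thr) - target,
                lo, hi, xtol=1e-8, rtol=1e-12)
    design = Design(n0=float(n0), ratios=tuple(ratios))
    achieved = power_at(design.n0, spec, ratios, thr)

    integer_design = achieved_int = None
    thr_final = thr
    if spec.integer_n:
        integer_design = design.rounded_up()
        # recalibrate Dunnett-type thresholds to the rounded ratios
        thr_final = thresholds(
            spec.mcc, spec.alpha, spec.K,
            covariance=null_covariance(spec, integer_design.ratios))
        achieved_int = power_at(integer_design.n0, spec,
                                integer_design.ratios, thr_final)
    return SampleSizeResult(
        design=design, thresholds=thr_final, power_type=requirement.power_type,
        target=target, achieved_power=float(achieved),
        integer_design=integer_design, achieved_power_integer=achieved_int)
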