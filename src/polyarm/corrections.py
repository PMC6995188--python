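"""The nine multiple-comparison corrections.

Each correction is represented by a vector of significance thresholds
gamma = (gamma_1, ..., gamma_K) together with a rule family:

* ``single_step`` — reject H_k iff p_k <= gamma (all gammas equal);
* ``step_down``   — Holm-type: ranking p ascending, find the smallest rank
  with p_(k) > gamma_k and reject all lower ranks (this classical rule is
  the one with strong familywise error control);
* ``step_up``     — Hochberg/Benjamini-type: find the largest rank with
  p_(k) <= gamma_k and reject it and all lower ranks.

Dunnett-type thresholds solve a K-dimensional MVN equation and therefore
require the covariance of the Wald statistics; the step-down Dunnett
correction additionally requires exchangeable correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from . import mvnorm
from .model import MCCS

__all__ = [
    "CorrectionThresholds",
    "thresholds",
    "dunnett_critical",
    "stepdown_dunnett_thresholds",
    "apply_correction",
    "apply_correction_matrix",
]

_FAMILY = {
    "none": "single_step",
    "bonferroni": "single_step",
    "sidak": "single_step",
    "dunnett": "single_step",
    "holm_bonferroni": "step_down",
    "holm_sidak": "step_down",
    "stepdown_dunnett": "step_down",
    "hochberg": "step_up",
    "benjamini_hochberg": "step_up",
    "benjamini_yekutieli": "step_up",
}


class UnsupportedConfigurationError(ValueError):
    """Raised for configurations the method does not cover (e.g. the
    step-down Dunnett correction with non-exchangeable correlations)."""


@dataclass(frozen=True)
class CorrectionThresholds:
    """Per-rank significance thresholds for one correction."""

    mcc: str
    gammas: tuple
    family: str

    def __post_init__(self):
        g = np.asarray(self.gammas, dtype=float)
        if np.any((g <= 0) | (g >= 1)):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.family == "single_step" and not np.allclose(g, g[0]):
            raise ValueError("single-step thresholds must be constant")
        if self.family in ("step_down", "step_up") and np.any(np.diff(g) < -1e-12):
            raise ValueError("step-wise thresholds must be non-decreasing in rank")

    @property
    def K(self) -> int:
        return len(self.gammas)

    @property
    def z_critical(self) -> np.ndarray:
        """Per-rank critical values on the z scale (non-increasing)."""
        return ndtri(1.0 - np.asarray(self.gammas))


def dunnett_critical(alpha: float, covariance: np.ndarray) -> float:
    """Critical value z_D solving alpha = 1 - Phi_K((z_D,...,z_D); 0, Cov)."""
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    K = cov.shape[0]
    c = mvnorm.loadings_from_cov(cov)
    eta = np.zeros(K)

    def f(z):
        return (1.0 - mvnorm.orthant_leq(z, eta, c)) - alpha

    try:
        return brentq(f, -10.0, 10.0, xtol=1e-10, rtol=1e-14)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ArithmeticError("Dunnett critical value not bracketed in [-10, 10]") from exc


def stepdown_dunnett_thresholds(alpha: float,
                                covariance: np.ndarray) -> CorrectionThresholds:
    """Step-down Dunnett thresholds; requires exchangeable correlations."""
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    K = cov.shape[0]
    off = cov[~np.eye(K, dtype=bool)]
    if K > 1 and not np.allclose(off, off[0], atol=1e-9):
        raise UnsupportedConfigurationError(
            "step-down Dunnett requires equal correlations between all "
            "pairs of test statistics")
    gammas = []
    for k in range(1, K + 1):
        sub = cov[: K + 1 - k, : K + 1 - k]
        zdk = dunnett_critical(alpha, sub)
        gammas.append(1.0 - ndtr(zdk))
    return CorrectionThresholds("stepdown_dunnett", tuple(gammas), "step_down")


def thresholds(mcc: str, alpha: float, K: int,
               covariance: np.ndarray | None = None) -> CorrectionThresholds:
    """Significance thresholds gamma_1..gamma_K for a correction.

    ``covariance`` (of the Wald statistics, normally under the global
    null) is required only for the Dunnett variants.
    """
    if mcc not in MCCS:
        raise ValueError(f"unknown correction {mcc!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    ks = np.arange(1, K + 1)
    fam = _FAMILY[mcc]
    if mcc == "none":
        g = np.full(K, alpha)
    elif mcc == "bonferroni":
        g = np.full(K, alpha / K)
    elif mcc == "sidak":
        g = np.full(K, 1.0 - (1.0 - alpha) ** (1.0 / K))
    elif mcc == "dunnett":
        if covariance is None:
            raise ValueError("Dunnett thresholds need the covariance of Z")
        zd = dunnett_critical(alpha, covariance)
        g = np.full(K, 1.0 - ndtr(zd))
    elif mcc == "holm_bonferroni":
        g = alpha / (K + 1 - ks)
    elif mcc == "holm_sidak":
        g = 1.0 - (1.0 - alpha) ** (1.0 / (K + 1 - ks))
    elif mcc == "stepdown_dunnett":
        if covariance is None:
            raise ValueError("step-down Dunnett thresholds need the covariance of Z")
        return stepdown_dunnett_thresholds(alpha, covariance)
    elif mcc == "hochberg":
        g = alpha / (K + 1 - ks)
    elif mcc == "benjamini_hochberg":
        g = ks * alpha / K
    else:  # benjamini_yekutieli
        g = ks * alpha / (K * np.sum(1.0 / ks))
    return CorrectionThresholds(mcc, tuple(g), fam)


def apply_correction_matrix(p: np.ndarray,
                            thr: CorrectionThresholds) -> np.ndarray:
    """Vectorised rejection rule: p has shape (n, K); returns booleans."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    n, K = p.shape
    if K != thr.K:
        raise ValueError("p-value vector length does not match thresholds")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    g = np.asarray(thr.gammas)
    if thr.family == "single_step":
        return p <= g[0]
    order = np.argsort(p, axis=1, kind="stable")
    sp = np.take_along_axis(p, order, axis=1)
    ok = sp <= g
    reject_rank = np.empty_like(ok)
    if thr.family == "step_down":
        # reject ranks strictly before the first failure
        reject_rank = np.cumprod(ok, axis=1).astype(bool)
    else:  # step_up
        # reject up to and including the last success
        reject_rank = np.flip(np.cumsum(np.flip(ok, axis=1), axis=1), axis=1) > 0
    out = np.zeros_like(ok)
    np.put_along_axis(out, order, reject_rank, axis=1)
    return out


def apply_correction(p, thr: CorrectionThresholds) -> np.ndarray:
    """Rejection indicators for a single p-value vector."""
    return apply_correction_matrix(np.asarray(p)[None, :], thr)[0]
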