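"""Colocalization of two association signals on a shared variant grid.

Given per-variant log approximate Bayes factors for two traits and
per-variant priors, computes posterior probabilities for the five
hypotheses of the single-causal-variant colocalization model:

    H0 no association; H1/H2 one trait only; H3 two distinct causal
    variants; H4 one shared causal variant.

Unnormalized weights (BF_i = exp(log ABF_i)):

    H0: 1
    H1: p1 * L1,           L1 = sum_i BF1_i
    H2: p2 * L2,           L2 = sum_j BF2_j
    H3: p1*p2 * (L1*L2 - S)
    H4: p12 * S,           S  = sum_i BF1_i * BF2_i

All sums are carried in log space; the H3 cancellation is evaluated
with a signed log-sum-exp and clamped at zero if it goes numerically
negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant priors of association with trait 1, trait 2, or both."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")


@dataclass(frozen=True)
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def colocalize(log_abf_1, log_abf_2,
               priors: ColocPriors = ColocPriors()) -> ColocResult:
    """Posterior probabilities PP0..PP4 from two log-ABF vectors."""
    la1 = np.asarray(log_abf_1, dtype=float)
    la2 = np.asarray(log_abf_2, dtype=float)
    if la1.shape != la2.shape or la1.ndim != 1 or la1.size < 1:
        raise ValueError("log-ABF vectors must share one non-empty grid")

    l1 = logsumexp(la1)
    l2 = logsumexp(la2)
    s = logsumexp(la1 + la2)
    # log(L1*L2 - S), signed; exact cancellation happens for n = 1
    log_h3_sum, sign = logsumexp([l1 + l2, s], b=[1.0, -1.0],
                                 return_sign=True)
    if sign <= 0 or not np.isfinite(log_h3_sum):
        if la1.size > 1:
            warnings.warn("H3 weight numerically non-positive; clamped to 0",
                          RuntimeWarning, stacklevel=2)
        log_h3_sum = -np.inf

    logw = np.array([
        0.0,
        np.log(priors.p1) + l1,
        np.log(priors.p2) + l2,
        np.log(priors.p1) + np.log(priors.p2) + log_h3_sum,
        np.log(priors.p12) + s,
    ])
    pp = softmax(logw)
    return ColocResult(*map(float, pp))


def is_colocalized(result: ColocResult, threshold: float = 0.80) -> bool:
    """Shared-causal call: PP4 strictly greater than ``threshold``."""
    return result.pp4 > threshold
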