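"""Annotation enrichment of association signals, one annotation at a time.

A hierarchical window model over GWAS summary statistics: the genome is
partitioned into fixed-size windows (default 1 Mb); each window harbors
at most one association, with prior probability Pi; given an
association, variant i in window k is the causal one with probability

    w_i = exp(gamma * a_i) / sum_{j in k} exp(gamma * a_j),

where a_i is a binary annotation indicator and gamma is the natural-log
enrichment of the annotation among causal variants. The marginal
likelihood multiplies over windows:

    L(gamma, Pi) = prod_k [ (1 - Pi) + Pi * sum_{i in k} w_i * ABF_i ],

with per-variant Wakefield approximate Bayes factors. gamma and Pi are
estimated jointly by maximum likelihood (Pi on the logit scale) and the
95% CI on gamma comes from the profile likelihood at the chi-square(1)
cutoff (a log-likelihood drop of 1.92).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .finemap import DEFAULT_PRIOR_VARIANCE, log_abf

_CHI2_95_HALF = 1.9207  # 0.5 * qchisq(0.95, df=1)


class EnrichmentError(RuntimeError):
    pass


@dataclass(frozen=True)
class WindowedGenome:
    """Variant table with window assignment and annotation indicator.

    ``variants`` carries at least ``variant_id, chrom, pos, window,
    annotated``; windows are ``window_size`` partitions per chromosome
    (index floor((pos-1)/window_size)).
    """

    variants: pd.DataFrame
    window_size: int


@dataclass(frozen=True)
class EnrichmentFit:
    gamma_hat: float
    ci_lo: float
    ci_hi: float
    pi_hat: float
    log_likelihood: float
    degenerate: bool = False


def partition_windows(records: pd.DataFrame,
                      annotation: pd.DataFrame | None = None,
                      window_size: int = 1_000_000) -> WindowedGenome:
    """Assign variants to fixed-size windows and attach annotation flags.

    Positions are 1-based; window index is ``floor((pos-1)/window_size)``
    per chromosome. A variant is annotated when its position falls
    inside any interval of the 0-based half-open ``annotation`` table
    (columns ``chrom, start, end``).
    """
    df = records.copy()
    if df["pos"].isna().any():
        raise ValueError("variants without position")
    widx = ((df["pos"].astype(np.int64) - 1) // window_size)
    df["window"] = df["chrom"].astype(str) + ":" + widx.astype(str)
    df["annotated"] = _annotate(df, annotation)
    return WindowedGenome(variants=df, window_size=window_size)


def _annotate(df: pd.DataFrame, annotation: pd.DataFrame | None) -> np.ndarray:
    flags = np.zeros(len(df), dtype=bool)
    if annotation is None or len(annotation) == 0:
        return flags
    for chrom, sub in annotation.groupby("chrom"):
        mask = (df["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        # merge to disjoint sorted intervals, then one searchsorted pass
        ivs = sub.sort_values("start")[["start", "end"]].to_numpy()
        starts, ends = _merge_intervals(ivs)
        pos0 = df.loc[mask, "pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        j = np.searchsorted(starts, pos0, side="right")
        hit = (j > 0) & (pos0 < ends[np.maximum(j - 1, 0)])
        flags[mask] = hit
    return flags


def _merge_intervals(ivs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    starts, ends = [], []
    for s, e in ivs:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _grouped_logsumexp(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """log-sum-exp of ``values`` within contiguous groups given by starts."""
    m = np.maximum.reduceat(values, starts)
    rep = np.diff(np.append(starts, len(values)))
    shifted = np.exp(values - np.repeat(m, rep))
    return m + np.log(np.add.reduceat(shifted, starts))


class _Likelihood:
    """Window-wise marginal log-likelihood, vectorized over variants."""

    def __init__(self, windowed: WindowedGenome, log_abfs: np.ndarray):
        df = windowed.variants
        order = np.argsort(df["window"].to_numpy(), kind="stable")
        win = df["window"].to_numpy()[order]
        self.a = df["annotated"].to_numpy(dtype=float)[order]
        self.log_abf = np.asarray(log_abfs, dtype=float)[order]
        self.starts = np.flatnonzero(np.r_[True, win[1:] != win[:-1]])
        self.n_windows = len(self.starts)

    def loglik(self, gamma: float, pi: float) -> float:
        ga = gamma * self.a
        log_w = ga - np.repeat(_grouped_logsumexp(ga, self.starts),
                               np.diff(np.append(self.starts, len(ga))))
        s_k = _grouped_logsumexp(log_w + self.log_abf, self.starts)
        terms = np.logaddexp(np.log1p(-pi), np.log(pi) + s_k)
        return float(terms.sum())

    def profile(self, gamma: float) -> float:
        """Max over Pi of the log-likelihood at fixed gamma."""
        res = optimize.minimize_scalar(
            lambda t: -self.loglik(gamma, _expit(t)),
            bounds=(-12, 12), method="bounded",
            options={"xatol": 1e-7})
        return -res.fun


def _expit(t):
    return 1.0 / (1.0 + np.exp(-t))


def _logit(p):
    return np.log(p / (1 - p))


def fit_enrichment(windowed: WindowedGenome, log_abfs,
                   gamma_bounds: tuple[float, float] = (-10.0, 10.0),
                   min_windows: int = 10) -> EnrichmentFit:
    """Joint ML fit of (gamma, Pi) with a profile-likelihood CI on gamma."""
    a = windowed.variants["annotated"].to_numpy()
    if a.all() or not a.any():
        raise EnrichmentError(
            "gamma unidentifiable: annotation constant across variants")
    lik = _Likelihood(windowed, np.asarray(log_abfs, dtype=float))
    if lik.n_windows < min_windows:
        raise EnrichmentError(f"need at least {min_windows} windows")

    def nll(theta):
        return -lik.loglik(theta[0], _expit(theta[1]))

    res = optimize.minimize(nll, x0=np.array([0.0, _logit(0.01)]),
                            method="L-BFGS-B",
                            bounds=[gamma_bounds, (-12, 12)],
                            options={"ftol": 1e-12, "gtol": 1e-9})
    if not res.success:
        # flat-likelihood robustness: profile over a gamma grid
        grid = np.linspace(gamma_bounds[0], gamma_bounds[1], 20)
        prof = [lik.profile(g) for g in grid]
        gbest = grid[int(np.argmax(prof))]
        res = optimize.minimize(nll, x0=np.array([gbest, _logit(0.01)]),
                                method="L-BFGS-B",
                                bounds=[gamma_bounds, (-12, 12)],
                                options={"ftol": 1e-12, "gtol": 1e-9})
        if not res.success:
            raise EnrichmentError(f"enrichment fit failed: {res.message}")
    gamma_hat = float(res.x[0])
    pi_hat = float(_expit(res.x[1]))
    ll_max = -float(res.fun)

    # flat likelihood (e.g. all ABFs equal): no information on gamma
    probe = np.linspace(gamma_bounds[0], gamma_bounds[1], 7)
    if max(lik.profile(g) for g in probe) - min(lik.profile(g) for g in probe) < 1e-9:
        return EnrichmentFit(gamma_hat=0.0, ci_lo=-np.inf, ci_hi=np.inf,
                             pi_hat=pi_hat, log_likelihood=ll_max,
                             degenerate=True)

    cutoff = ll_max - _CHI2_95_HALF
    ci_lo = _profile_bound(lik, gamma_hat, cutoff, gamma_bounds[0])
    ci_hi = _profile_bound(lik, gamma_hat, cutoff, gamma_bounds[1])
    return EnrichmentFit(gamma_hat=gamma_hat, ci_lo=ci_lo, ci_hi=ci_hi,
                         pi_hat=pi_hat, log_likelihood=ll_max)


def _profile_bound(lik: _Likelihood, gamma_hat: float, cutoff: float,
                   limit: float) -> float:
    """Root of profile(gamma) = cutoff between gamma_hat and ``limit``."""
    f = lambda g: lik.profile(g) - cutoff
    if f(limit) > 0:        # profile never drops below the cutoff
        return limit if np.isfinite(limit) else np.sign(limit) * np.inf
    lo, hi = sorted((gamma_hat, limit))
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


def enrichment_analysis(records: pd.DataFrame, annotation: pd.DataFrame,
                        window_size: int = 1_000_000,
                        maf_threshold: float = 0.05,
                        prior_variance: float = DEFAULT_PRIOR_VARIANCE
                        ) -> EnrichmentFit:
    """MAF-filter summary stats, window them, and fit the enrichment model."""
    from .finemap import maf_filter
    recs = maf_filter(records, maf_threshold)
    windowed = partition_windows(recs, annotation, window_size)
    la = log_abf(windowed.variants["beta"].to_numpy(),
                 windowed.variants["se"].to_numpy(), prior_variance)
    return fit_enrichment(windowed, la)
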