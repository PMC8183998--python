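"""Allelic imbalance in chromatin accessibility at heterozygous SNPs.

Workflow: per-sample allele counts are filtered for depth and minimum
allele observations, merged across samples within each condition, a
two-parameter beta-binomial null is fitted to the merged counts by
maximum likelihood, each variant is tested for imbalance with an exact
two-sided beta-binomial test, and variants imbalanced in either
condition are tested for cross-condition heterogeneity with a Yates-
corrected chi-squared test (the behaviour of R's ``prop.test``).

Input records are rows of a DataFrame with columns ``variant_id, chrom,
pos, sample_id, condition, ref_count, alt_count``; conditions are the
two labels ``treated`` and ``untreated``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("treated", "untreated")

COUNT_COLUMNS = ["variant_id", "chrom", "pos", "sample_id", "condition",
                 "ref_count", "alt_count"]


class FitError(RuntimeError):
    """Beta-binomial maximum-likelihood fit failed; carries last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class BetaBinomialParams:
    """Shape parameters of a beta-binomial null for merged allele counts.

    The intraclass-correlation overdispersion is the derived quantity
    rho = 1 / (alpha + beta + 1); rho -> 0 recovers the binomial.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"shape parameters must be positive, got alpha={self.alpha}, "
                f"beta={self.beta}")

    @property
    def overdispersion(self) -> float:
        return 1.0 / (self.alpha + self.beta + 1.0)

    @property
    def mean_ref_fraction(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cross-condition difference in allelic ratio at one variant."""

    variant_id: str
    ref_fraction_treated: float
    ref_fraction_untreated: float
    chi2_stat: float
    p_value: float


def overdispersion(params: BetaBinomialParams) -> float:
    """Intraclass correlation rho = 1/(alpha+beta+1) of a beta-binomial."""
    return params.overdispersion


def filter_and_merge_counts(records: pd.DataFrame, min_depth: int = 10,
                            min_allele_obs: int = 3) -> pd.DataFrame:
    """Filter per-sample het-SNP counts and merge across samples.

    A variant is retained for a sample only if that sample has depth
    >= ``min_depth`` in *both* conditions and each allele is observed
    >= ``min_allele_obs`` times summed over the sample's two conditions.
    Retained per-sample counts are then summed across samples within
    each condition.

    Returns a DataFrame with columns ``variant_id, condition, ref_count,
    alt_count, ref_fraction``.
    """
    df = records.copy()
    missing = set(("variant_id", "sample_id", "condition",
                   "ref_count", "alt_count")) - set(df.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ValueError("negative allele counts")
    bad = set(df["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    if df.empty:
        return pd.DataFrame(columns=["variant_id", "condition", "ref_count",
                                     "alt_count", "ref_fraction"])

    # collapse duplicate rows per (variant, sample, condition), then pivot
    per = (df.groupby(["variant_id", "sample_id", "condition"], sort=False)
             [["ref_count", "alt_count"]].sum().reset_index())
    wide = per.pivot_table(index=["variant_id", "sample_id"],
                           columns="condition",
                           values=["ref_count", "alt_count"])
    for cond in CONDITIONS:
        for col in ("ref_count", "alt_count"):
            if (col, cond) not in wide.columns:
                wide[(col, cond)] = np.nan

    depth_t = wide[("ref_count", "treated")] + wide[("alt_count", "treated")]
    depth_u = wide[("ref_count", "untreated")] + wide[("alt_count", "untreated")]
    ref_tot = wide[("ref_count", "treated")] + wide[("ref_count", "untreated")]
    alt_tot = wide[("alt_count", "treated")] + wide[("alt_count", "untreated")]
    keep = ((depth_t >= min_depth) & (depth_u >= min_depth)
            & (ref_tot >= min_allele_obs) & (alt_tot >= min_allele_obs))
    keep = keep.fillna(False)
    kept = wide.loc[keep]

    rows = []
    for cond in CONDITIONS:
        sub = (kept[[("ref_count", cond), ("alt_count", cond)]]
               .droplevel("sample_id"))
        sub.columns = ["ref_count", "alt_count"]
        merged = sub.groupby("variant_id", sort=True).sum()
        merged["condition"] = cond
        rows.append(merged.reset_index())
    out = pd.concat(rows, ignore_index=True)
    out[["ref_count", "alt_count"]] = out[["ref_count", "alt_count"]].astype(int)
    depth = out["ref_count"] + out["alt_count"]
    out["ref_fraction"] = np.where(depth > 0, out["ref_count"] / depth, np.nan)
    return out[["variant_id", "condition", "ref_count", "alt_count",
                "ref_fraction"]]


def _negative_loglik(log_shapes, ref, total):
    a, b = np.exp(log_shapes)
    return -stats.betabinom.logpmf(ref, total, a, b).sum()


def fit_beta_binomial(ref_counts, total_counts) -> BetaBinomialParams:
    """Maximum-likelihood two-parameter beta-binomial fit over variants.

    ``ref_count[i] | total[i] ~ BetaBinomial(total[i], alpha, beta)``.
    Optimized in log-shape space from a method-of-moments start.
    """
    ref = np.asarray(ref_counts, dtype=float)
    total = np.asarray(total_counts, dtype=float)
    pos = total > 0
    if pos.sum() < 2:
        raise ValueError("need at least two variants with positive depth")
    ref, total = ref[pos], total[pos]

    # method-of-moments start: match mean fraction and excess variance
    frac = ref / total
    p0 = float(np.clip(frac.mean(), 1e-3, 1 - 1e-3))
    var_excess = frac.var() - np.mean(p0 * (1 - p0) / total)
    rho0 = float(np.clip(var_excess / (p0 * (1 - p0)), 1e-4, 0.5))
    conc0 = 1.0 / rho0 - 1.0
    x0 = np.log([p0 * conc0, (1 - p0) * conc0])

    res = optimize.minimize(_negative_loglik, x0, args=(ref, total),
                            method="L-BFGS-B",
                            bounds=[(-10, 15)] * 2,
                            options={"ftol": 1e-10, "gtol": 1e-8,
                                     "maxiter": 500})
    if not res.success and not np.isfinite(res.fun):
        raise FitError(f"beta-binomial fit failed: {res.message}",
                       last_params=np.exp(res.x))
    a, b = np.exp(res.x)
    return BetaBinomialParams(alpha=float(a), beta=float(b))


def test_imbalance(ref: int, alt: int, params: BetaBinomialParams) -> float:
    """Exact two-sided beta-binomial test of allelic imbalance.

    p is the total beta-binomial probability of all outcomes k in 0..n
    whose pmf does not exceed the pmf of the observed ref count
    (minimum-likelihood ordering).
    """
    n = ref + alt
    if n < 1:
        raise ValueError("total depth must be >= 1")
    pmf = stats.betabinom.pmf(np.arange(n + 1), n, params.alpha, params.beta)
    p = pmf[pmf <= pmf[ref] * (1 + 1e-10)].sum()
    return float(min(p, 1.0))


def test_imbalance_many(ref_counts, total_counts,
                        params: BetaBinomialParams) -> np.ndarray:
    """Vectorized exact test for many variants, grouped by total depth."""
    ref = np.asarray(ref_counts, dtype=int)
    total = np.asarray(total_counts, dtype=int)
    if (total < 1).any():
        raise ValueError("total depth must be >= 1")
    p = np.empty(len(ref), dtype=float)
    for n in np.unique(total):
        idx = np.flatnonzero(total == n)
        pmf = stats.betabinom.pmf(np.arange(n + 1), n,
                                  params.alpha, params.beta)
        thresh = pmf[ref[idx]] * (1 + 1e-10)
        p[idx] = np.minimum((pmf[None, :] <= thresh[:, None]) @ pmf, 1.0)
    return p


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def heterogeneity_test(ref1: int, alt1: int, ref2: int,
                       alt2: int) -> tuple[float, float]:
    """Yates-corrected 2x2 chi-squared for a shift in allelic ratio.

    Condition 1 vs condition 2, alleles as columns; matches R's
    ``prop.test`` (continuity correction floored so chi2 >= 0).
    Returns ``(chi2, p)``.
    """
    if ref1 + alt1 == 0 or ref2 + alt2 == 0:
        raise ValueError("both conditions need positive depth")
    table = np.array([[ref1, alt1], [ref2, alt2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        # one allele absent in both conditions: no evidence of difference
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def imbalance_scan(merged: pd.DataFrame,
                   params_by_condition: dict[str, BetaBinomialParams] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, BetaBinomialParams]]:
    """Per-condition imbalance p/q values on merged counts.

    Fits the beta-binomial null per condition unless ``params_by_condition``
    supplies shapes. Returns the result table (one row per variant x
    condition, with p and BH q) and the shape parameters used.
    """
    params_by_condition = dict(params_by_condition or {})
    frames = []
    for cond, sub in merged.groupby("condition", sort=True):
        sub = sub[sub["ref_count"] + sub["alt_count"] > 0].copy()
        if cond not in params_by_condition:
            params_by_condition[cond] = fit_beta_binomial(
                sub["ref_count"].to_numpy(),
                (sub["ref_count"] + sub["alt_count"]).to_numpy())
        pars = params_by_condition[cond]
        sub["p_value"] = test_imbalance_many(
            sub["ref_count"].to_numpy(),
            (sub["ref_count"] + sub["alt_count"]).to_numpy(), pars)
        sub["q_value"] = bh_qvalues(sub["p_value"].to_numpy())
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out, params_by_condition


def heterogeneity_scan(imbalance_results: pd.DataFrame,
                       fdr: float = 0.10) -> pd.DataFrame:
    """Heterogeneity test for variants imbalanced in either condition.

    Takes the output of :func:`imbalance_scan`; variants with q < fdr in
    at least one condition and counts in both conditions are tested.
    """
    wide = imbalance_results.pivot(index="variant_id", columns="condition")
    have_both = (wide[("ref_count", "treated")].notna()
                 & wide[("ref_count", "untreated")].notna())
    signif = ((wide[("q_value", "treated")] < fdr).fillna(False)
              | (wide[("q_value", "untreated")] < fdr).fillna(False))
    sel = wide.loc[have_both & signif]
    rows = []
    for vid, row in sel.iterrows():
        rt, at_ = int(row[("ref_count", "treated")]), int(row[("alt_count", "treated")])
        ru, au = int(row[("ref_count", "untreated")]), int(row[("alt_count", "untreated")])
        chi2, p = heterogeneity_test(rt, at_, ru, au)
        rows.append({"variant_id": vid,
                     "ref_fraction_treated": rt / (rt + at_),
                     "ref_fraction_untreated": ru / (ru + au),
                     "chi2_stat": chi2, "p_value": p})
    out = pd.DataFrame(rows, columns=["variant_id", "ref_fraction_treated",
                                      "ref_fraction_untreated", "chi2_stat",
                                      "p_value"])
    if len(out):
        out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
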