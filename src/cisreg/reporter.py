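"""Dual-luciferase reporter normalization and allelic-effect tests.

Wells are rows of a DataFrame with columns ``construct`` (ref, alt or
empty), ``treatment`` (treated or untreated), ``batch``, ``firefly``
and ``renilla``. Firefly is normalized to renilla per well, expressed
as fold change over the mean empty-vector ratio of the same treatment,
and batch effects are removed by centering log2 fold per batch and
restoring the grand mean. Allelic effects are tested with a two-sided
Welch t-test per treatment, and the treatment dependence of the
allelic ratio with a permutation test of the allele labels (permuted
within each treatment stratum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WELL_COLUMNS = ["construct", "treatment", "batch", "firefly", "renilla"]
CONSTRUCTS = ("ref", "alt", "empty")


@dataclass(frozen=True)
class AllelicRatio:
    """Ratio of geometric-mean fold changes (ref / alt) with 95% CI."""

    ratio: float
    ci_lo: float
    ci_hi: float


@dataclass(frozen=True)
class ReporterResult:
    folds: pd.DataFrame
    ttest_p: dict            # treatment -> Welch p, ref vs alt log2 folds
    allelic_ratio: dict      # treatment -> AllelicRatio
    ratio_of_ratios: float   # (ref/alt treated) / (ref/alt untreated)
    permutation_p: float
    n_perm: int
    seed: int


def _check_wells(wells: pd.DataFrame) -> None:
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"well table lacks columns: {sorted(missing)}")
    if (wells["firefly"] <= 0).any() or (wells["renilla"] <= 0).any():
        raise ValueError("luminescence readings must be positive")
    bad = set(wells["construct"].unique()) - set(CONSTRUCTS)
    if bad:
        raise ValueError(f"unknown constructs: {sorted(bad)}")


def normalize_luciferase(wells: pd.DataFrame,
                         batch_correct: bool = True) -> pd.DataFrame:
    """Per-well fold change over the empty vector, batch-corrected.

    ratio = firefly/renilla; fold = ratio / mean(empty-vector ratios of
    the same treatment). With ``batch_correct``, log2 folds are centred
    per batch and the grand mean restored (identity for a single
    batch). Returns the well table with ``ratio``, ``fold`` and
    ``log2_fold`` columns added.
    """
    _check_wells(wells)
    df = wells.copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    empties = df[df["construct"] == "empty"]
    for batch in df["batch"].unique():
        if not (empties["batch"] == batch).any():
            raise ValueError(f"batch {batch!r} has no empty-vector wells")
    empty_mean = empties.groupby("treatment")["ratio"].mean()
    if not set(df["treatment"]) <= set(empty_mean.index):
        raise ValueError("a treatment lacks empty-vector wells")
    df["fold"] = df["ratio"] / df["treatment"].map(empty_mean).to_numpy()
    log2f = np.log2(df["fold"].to_numpy())
    if batch_correct:
        grand = log2f.mean()
        batch_mean = pd.Series(log2f).groupby(df["batch"].to_numpy()).transform("mean")
        log2f = log2f - batch_mean.to_numpy() + grand
    df["log2_fold"] = log2f
    df["fold"] = 2.0 ** log2f
    return df


def allele_ttest(folds_ref, folds_alt) -> float:
    """Two-sided Welch t-test on log2 fold changes, ref vs alt wells."""
    fr = np.asarray(folds_ref, dtype=float)
    fa = np.asarray(folds_alt, dtype=float)
    if fr.size < 2 or fa.size < 2:
        raise ValueError("need at least two wells per allele")
    if (fr <= 0).any() or (fa <= 0).any():
        raise ValueError("fold changes must be positive")
    t, p = stats.ttest_ind(np.log2(fr), np.log2(fa), equal_var=False)
    return float(p)


def _geo_ratio(ref: np.ndarray, alt: np.ndarray) -> AllelicRatio:
    lr, la = np.log2(ref), np.log2(alt)
    diff = lr.mean() - la.mean()
    se = np.sqrt(lr.var(ddof=1) / len(lr) + la.var(ddof=1) / len(la))
    # Welch-Satterthwaite df for the CI on the log2 difference
    v1, v2 = lr.var(ddof=1) / len(lr), la.var(ddof=1) / len(la)
    if v1 + v2 > 0:
        df = (v1 + v2) ** 2 / (v1 ** 2 / (len(lr) - 1) + v2 ** 2 / (len(la) - 1))
        half = stats.t.ppf(0.975, df) * se
    else:
        half = 0.0
    return AllelicRatio(ratio=float(2.0 ** diff),
                        ci_lo=float(2.0 ** (diff - half)),
                        ci_hi=float(2.0 ** (diff + half)))


def allelic_ratio_permutation(ref_treated, alt_treated, ref_untreated,
                              alt_untreated, n_perm: int = 100_000,
                              seed: int = 0) -> tuple[float, float]:
    """Permutation test for a treatment-dependent allelic ratio.

    Statistic T = |log((mean ref_t / mean alt_t) / (mean ref_u /
    mean alt_u))| on fold changes. The null permutes allele labels
    within each treatment independently; p uses the add-one estimator
    (1 + #{T_perm >= T_obs}) / (1 + n_perm). Returns (observed
    ratio-of-ratios, p).
    """
    groups = [np.asarray(g, dtype=float) for g in
              (ref_treated, alt_treated, ref_untreated, alt_untreated)]
    if any(g.size < 2 for g in groups):
        raise ValueError("need at least two wells per group")
    if any((g <= 0).any() for g in groups):
        raise ValueError("fold changes must be positive")
    rt, at_, ru, au = groups

    obs_ratio = (rt.mean() / at_.mean()) / (ru.mean() / au.mean())
    t_obs = abs(np.log(obs_ratio))

    rng = np.random.default_rng(seed)
    log_t = _permuted_log_ratios(rt, at_, n_perm, rng)
    log_u = _permuted_log_ratios(ru, au, n_perm, rng)
    t_perm = np.abs(log_t - log_u)
    p = (1 + int((t_perm >= t_obs - 1e-12).sum())) / (1 + n_perm)
    return float(obs_ratio), float(p)


def _permuted_log_ratios(ref: np.ndarray, alt: np.ndarray, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """log(mean 'ref' / mean 'alt') under random allele labelings."""
    pool = np.concatenate([ref, alt])
    n, k = len(pool), len(ref)
    total = pool.sum()
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    ref_sum = pool[order[:, :k]].sum(axis=1)
    return np.log((ref_sum / k) / ((total - ref_sum) / (n - k)))


def reporter_analysis(wells: pd.DataFrame, n_perm: int = 100_000,
                      seed: int = 0) -> ReporterResult:
    """Normalize wells and run the allele and treatment-interaction tests."""
    folds = normalize_luciferase(wells)

    def _grp(construct, treatment):
        sel = (folds["construct"] == construct) & (folds["treatment"] == treatment)
        return folds.loc[sel, "fold"].to_numpy()

    ttest_p, ratios = {}, {}
    for trt in ("treated", "untreated"):
        ref, alt = _grp("ref", trt), _grp("alt", trt)
        ttest_p[trt] = allele_ttest(ref, alt)
        ratios[trt] = _geo_ratio(ref, alt)
    rr, p_perm = allelic_ratio_permutation(
        _grp("ref", "treated"), _grp("alt", "treated"),
        _grp("ref", "untreated"), _grp("alt", "untreated"),
        n_perm=n_perm, seed=seed)
    return ReporterResult(folds=folds, ttest_p=ttest_p, allelic_ratio=ratios,
                          ratio_of_ratios=rr, permutation_p=p_perm,
                          n_perm=n_perm, seed=seed)
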