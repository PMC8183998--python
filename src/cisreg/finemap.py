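"""Wakefield approximate Bayes factors, PPAs and 99% credible sets.

Summary statistics (per-allele effect ``beta``, standard error ``se``,
minor allele frequency ``maf``, optional ``r2_to_index``) are turned
into log approximate Bayes factors under a normal effect prior of
variance ``W``; within a locus, posterior probabilities of association
assume a single causal variant (PPA_i = ABF_i / sum_j ABF_j) and the
credible set is the shortest descending-PPA prefix reaching the level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

DEFAULT_PRIOR_VARIANCE = 0.04  # prior sd 0.2 on the per-allele effect


@dataclass(frozen=True)
class CredibleSet:
    locus_id: str
    level: float
    variant_ids: tuple[str, ...]       # descending PPA
    ppa: tuple[float, ...]             # aligned with variant_ids
    cumulative_mass: float


def maf_filter(records: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Keep variants with MAF strictly greater than ``threshold``."""
    maf = records["maf"].to_numpy(dtype=float)
    if len(maf) and (((maf <= 0) | (maf > 0.5)).any() or np.isnan(maf).any()):
        raise ValueError("MAF values must lie in (0, 0.5]")
    return records.loc[maf > threshold].copy()


def log_abf(beta, se, prior_variance: float = DEFAULT_PRIOR_VARIANCE):
    """Natural-log Wakefield approximate Bayes factor for association.

    With V = se^2 and z = beta/se:
        log ABF = 0.5*log(V/(V+W)) + (z^2/2) * W/(V+W).
    Computed in log space; safe for |z| far beyond genome-wide
    significance.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    if prior_variance <= 0:
        raise ValueError("prior variance must be positive")
    V = se ** 2
    z2 = (beta / se) ** 2
    out = 0.5 * np.log(V / (V + prior_variance)) \
        + 0.5 * z2 * prior_variance / (V + prior_variance)
    return out if out.ndim else float(out)


def define_locus(index_id: str, records: pd.DataFrame,
                 window: float = 5_000_000, r2_min: float = 0.1) -> pd.DataFrame:
    """Variants forming the locus of an index variant.

    Same chromosome, within ``window/2`` of the index position (a
    window of total width ``window`` centred on the index), and in at
    least low linkage (r2 strictly above ``r2_min``). The index itself
    is always included with r2 = 1.
    """
    idx = records.loc[records["variant_id"] == index_id]
    if len(idx) != 1:
        raise ValueError(f"index variant {index_id!r} not found exactly once")
    idx = idx.iloc[0]
    if pd.isna(idx["pos"]):
        raise ValueError("index variant lacks a position")
    r2 = records["r2_to_index"].to_numpy(dtype=float)
    near = ((records["chrom"] == idx["chrom"])
            & ((records["pos"] - idx["pos"]).abs() <= window / 2))
    keep = (near & (r2 > r2_min)) | (records["variant_id"] == index_id)
    out = records.loc[keep].copy()
    out.loc[out["variant_id"] == index_id, "r2_to_index"] = 1.0
    return out


def posterior_probabilities(log_abfs) -> np.ndarray:
    """PPA_i = ABF_i / sum_j ABF_j via log-sum-exp (single causal variant)."""
    la = np.asarray(log_abfs, dtype=float)
    if la.size == 0:
        raise ValueError("empty locus")
    return softmax(la)


def credible_set(ppas, variant_ids, level: float = 0.99,
                 locus_id: str = "locus") -> CredibleSet:
    """Shortest descending-PPA prefix with cumulative mass >= ``level``.

    The variant whose inclusion crosses the level is included; PPA ties
    are broken by variant id so the set is deterministic.
    """
    ppa = np.asarray(ppas, dtype=float)
    ids = np.asarray(variant_ids, dtype=object)
    if abs(ppa.sum() - 1.0) > 1e-6:
        raise ValueError("PPAs are not normalized")
    order = np.lexsort((ids, -ppa))
    csum = np.cumsum(ppa[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    k = min(k, len(ppa))
    sel = order[:k]
    return CredibleSet(locus_id=locus_id, level=level,
                       variant_ids=tuple(ids[sel]),
                       ppa=tuple(ppa[sel]),
                       cumulative_mass=float(csum[k - 1]))


def fine_map(records: pd.DataFrame, index_id: str,
             window: float = 5_000_000, r2_min: float = 0.1,
             level: float = 0.99, maf_threshold: float = 0.05,
             prior_variance: float = DEFAULT_PRIOR_VARIANCE
             ) -> tuple[pd.DataFrame, CredibleSet]:
    """MAF filter -> locus definition -> ABF -> PPA -> credible set."""
    recs = maf_filter(records, maf_threshold)
    locus = define_locus(index_id, recs, window=window, r2_min=r2_min)
    locus = locus.copy()
    locus["log_abf"] = log_abf(locus["beta"].to_numpy(),
                               locus["se"].to_numpy(), prior_variance)
    locus["ppa"] = posterior_probabilities(locus["log_abf"].to_numpy())
    cs = credible_set(locus["ppa"].to_numpy(),
                      locus["variant_id"].to_numpy(), level=level,
                      locus_id=index_id)
    locus["in_credible_set"] = locus["variant_id"].isin(cs.variant_ids)
    return locus, cs
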