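"""Interval statistics relating chromatin sites to genes and TF binding.

Intervals are rows of DataFrames with columns ``chrom, start, end`` in
BED convention (0-based half-open), plus optional ``significance``
(smaller = more significant) and ``label``. Operations: merging peak
sets into canonical non-overlapping sites, Fisher proximity enrichment
of differential sites near differentially expressed genes, the relative
distance metric of interval-to-interval attraction, a two-sample
Kolmogorov-Smirnov comparison of relative-distance distributions, and
2x2 overlap enrichment against TF ChIP-seq binding sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

BED_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 overlap/proximity table with Fisher p, OR and fold-enrichment.

    Table rows are (differential, non-differential); columns are
    (positive, negative). odds_ratio = (a*d)/(b*c) with 0/0 -> nan and
    x/0 -> inf; fold = (a/(a+b)) / (c/(c+d)).
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    fold_enrichment: float
    p_value: float


def _validate(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = set(BED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing interval columns {sorted(missing)}")
    if len(df) and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
        raise ValueError(f"{name}: intervals must satisfy 0 <= start < end")
    return df


def merge_canonical_peaks(peak_sets) -> pd.DataFrame:
    """Resolve overlapping peaks across sets, keeping the more significant.

    All peaks are pooled and sorted by ascending significance value
    (smaller = more significant); a peak is accepted iff it overlaps no
    already-accepted peak. Output is coordinate-sorted. Determinism:
    ties in significance are broken by (chrom, start, end).
    """
    pooled = pd.concat(list(peak_sets), ignore_index=True)
    _validate(pooled, "peaks")
    if "significance" not in pooled.columns or pooled["significance"].isna().any():
        raise ValueError("all peaks need a significance value")
    pooled = pooled.sort_values(["significance", "chrom", "start", "end"],
                                kind="stable")
    trees: dict[str, IntervalTree] = {}
    accepted = []
    for row in pooled.itertuples(index=False):
        tree = trees.setdefault(row.chrom, IntervalTree())
        if not tree.overlap(row.start, row.end):
            tree.addi(row.start, row.end)
            accepted.append(row)
    out = pd.DataFrame(accepted, columns=pooled.columns)
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _merged_arrays(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome disjoint sorted (starts, ends) of the interval union."""
    out = {}
    for chrom, sub in df.groupby("chrom"):
        ivs = sub.sort_values("start")[["start", "end"]].to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def _gap_to_nearest(sites: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Gap (bp) from each site to its nearest target; 0 when overlapping
    or abutting; inf when the site's chromosome has no target."""
    merged = _merged_arrays(targets)
    gaps = np.full(len(sites), np.inf)
    chroms = sites["chrom"].to_numpy()
    for chrom, (tstarts, tends) in merged.items():
        loc = np.flatnonzero(chroms == chrom)
        if loc.size == 0:
            continue
        s = sites["start"].to_numpy()[loc]
        e = sites["end"].to_numpy()[loc]
        j = np.searchsorted(tstarts, e, side="left")
        # gap to the target starting at/after the site end
        right = np.where(j < len(tstarts),
                         tstarts[np.minimum(j, len(tstarts) - 1)] - e, np.inf)
        # gap to the nearest target before (or spanning) the site
        left = np.where(j > 0,
                        s - tends[np.maximum(j - 1, 0)], np.inf)
        gaps[loc] = np.minimum(np.maximum(right, 0), np.maximum(left, 0))
    return gaps


def _overlaps_any(sites: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """True where a site shares >= 1 bp with any target interval
    (abutting half-open intervals do not overlap)."""
    merged = _merged_arrays(targets)
    out = np.zeros(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    for chrom, (tstarts, tends) in merged.items():
        loc = np.flatnonzero(chroms == chrom)
        if loc.size == 0:
            continue
        s = sites["start"].to_numpy()[loc]
        e = sites["end"].to_numpy()[loc]
        j = np.searchsorted(tstarts, e, side="left")  # targets with start < e
        out[loc] = (j > 0) & (tends[np.maximum(j - 1, 0)] > s)
    return out


def _fisher(table: np.ndarray) -> ContingencyResult:
    a, b = table[0]
    c, d = table[1]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.float64(a * d) / np.float64(b * c)
        rate1 = a / (a + b) if a + b else np.nan
        rate2 = c / (c + d) if c + d else np.nan
        fold = np.float64(rate1) / np.float64(rate2)
    if not np.isfinite(fold):
        warnings.warn("zero background rate: fold-enrichment is infinite",
                      RuntimeWarning, stacklevel=3)
    return ContingencyResult(table=((int(a), int(b)), (int(c), int(d))),
                             odds_ratio=float(odds),
                             fold_enrichment=float(fold), p_value=float(p))


def proximity_fisher(diff_sites: pd.DataFrame, nondiff_sites: pd.DataFrame,
                     genes: pd.DataFrame, window: int = 100_000
                     ) -> ContingencyResult:
    """Fisher test: differential sites proximal to gene bodies vs background.

    A site is proximal when the gap between it and any gene-body
    interval is <= ``window`` (overlap counts as gap 0).
    """
    for df, name in ((diff_sites, "diff_sites"),
                     (nondiff_sites, "nondiff_sites"), (genes, "genes")):
        _validate(df, name)
    if len(genes) == 0:
        raise ValueError("empty gene set")
    near_d = _gap_to_nearest(diff_sites, genes) <= window
    near_n = _gap_to_nearest(nondiff_sites, genes) <= window
    table = np.array([[near_d.sum(), (~near_d).sum()],
                      [near_n.sum(), (~near_n).sum()]])
    return _fisher(table)


def relative_distance(a_intervals: pd.DataFrame,
                      b_intervals: pd.DataFrame) -> np.ndarray:
    """Relative distance of each A midpoint to its flanking B midpoints.

    d = min(|a - left|, |right - a|) / (right - left), in [0, 0.5];
    uniform on [0, 0.5] when A is placed independently of B. A
    midpoints outside the span of B midpoints (or on chromosomes with
    fewer than two B intervals) are skipped.
    """
    _validate(a_intervals, "a")
    _validate(b_intervals, "b")
    values = []
    b_mids = {chrom: np.sort((sub["start"] + sub["end"]).to_numpy() / 2.0)
              for chrom, sub in b_intervals.groupby("chrom")}
    for chrom, sub in a_intervals.groupby("chrom"):
        mids = b_mids.get(chrom)
        if mids is None or len(mids) < 2:
            warnings.warn(f"{chrom}: fewer than two reference intervals; "
                          f"{len(sub)} query intervals skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        a = (sub["start"] + sub["end"]).to_numpy() / 2.0
        inside = (a >= mids[0]) & (a <= mids[-1])
        a = a[inside]
        j = np.clip(np.searchsorted(mids, a, side="right"), 1, len(mids) - 1)
        left, right = mids[j - 1], mids[j]
        d = np.minimum(a - left, right - a) / (right - left)
        values.append(d)
    if not values:
        return np.empty(0)
    return np.concatenate(values)


def ks_compare(dist1, dist2) -> tuple[float, float]:
    """Two-sample two-sided KS statistic and asymptotic p-value."""
    d1 = np.asarray(dist1, dtype=float)
    d2 = np.asarray(dist2, dtype=float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("empty relative-distance distribution")
    res = stats.ks_2samp(d1, d2, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chip_overlap_enrichment(diff_sites: pd.DataFrame,
                            nondiff_sites: pd.DataFrame,
                            tf_sites: pd.DataFrame) -> ContingencyResult:
    """2x2 Fisher enrichment of TF binding-site overlap in differential
    sites versus non-differential sites (>= 1 bp intersection)."""
    for df, name in ((diff_sites, "diff_sites"),
                     (nondiff_sites, "nondiff_sites"), (tf_sites, "tf_sites")):
        _validate(df, name)
    ov_d = _overlaps_any(diff_sites, tf_sites)
    ov_n = _overlaps_any(nondiff_sites, tf_sites)
    table = np.array([[ov_d.sum(), (~ov_d).sum()],
                      [ov_n.sum(), (~ov_n).sum()]])
    return _fisher(table)
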