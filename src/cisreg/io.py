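"""Readers and writers for the pipeline's text formats.

Intervals travel as BED3+ (0-based half-open, tab-separated, optional
score column mapped to ``significance``); tabular inputs (allele
counts, summary statistics, reporter wells) are header-bearing TSVs
with 1-based variant positions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .imbalance import COUNT_COLUMNS
from .reporter import WELL_COLUMNS

STATS_COLUMNS = ["variant_id", "chrom", "pos", "beta", "se", "maf"]


class BedFormatError(ValueError):
    pass


def read_bed(path, sig_col: int | None = None) -> pd.DataFrame:
    """Read BED3+ intervals; ``sig_col`` (1-based column index) maps a
    numeric column onto ``significance``. Track/browser lines are
    skipped; errors name the offending line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line.strip() or line.startswith("track")
                    or line.startswith("browser") or line.startswith("#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: requires 0 <= start < end")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(fields) > 3:
                row["label"] = fields[3]
            if sig_col is not None:
                if len(fields) < sig_col:
                    raise BedFormatError(
                        f"{path}: line {lineno}: no column {sig_col}")
                try:
                    row["significance"] = float(fields[sig_col - 1])
                except ValueError:
                    raise BedFormatError(
                        f"{path}: line {lineno}: non-numeric score") from None
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    order = [c for c in ["chrom", "start", "end", "label", "significance"]
             if c in df.columns]
    return df[order]


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "label", "significance"]
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _read_tsv(path, required, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: {name} table lacks columns "
                         f"{sorted(missing)}")
    return df


def read_counts_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, COUNT_COLUMNS, "allele-count")


def read_stats_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, STATS_COLUMNS, "summary-statistic")


def read_wells_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, WELL_COLUMNS, "reporter-well")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
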