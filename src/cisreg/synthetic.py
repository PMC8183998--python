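"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its spec (identical seed, byte-
identical output) and emits planted ground truth alongside the data so
calibration and recovery can be tested downstream. The generators
emulate:

* beta-binomially overdispersed allele counts at heterozygous SNPs,
  with a logit-scale shift of the mean ref fraction at a subset of
  imbalanced variants, optionally in only one condition;
* GWAS-style summary statistics with block-constant LD and a planted
  causal variant of given non-centrality, singly or as a pair of
  traits sharing (or not sharing) the causal variant;
* windowed genomes in which causal variants prefer an annotation with
  a planted natural-log enrichment;
* interval sets with tunable attraction between the two sets;
* dual-luciferase wells with allele, treatment-interaction, batch and
  noise effects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .imbalance import CONDITIONS


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------- imbalance

@dataclass(frozen=True)
class ImbalanceSimSpec:
    n_variants: int = 2000
    n_samples_per_condition: int = 7
    mean_depth: float = 50.0
    alpha0: float = 40.78
    beta0: float = 39.26
    frac_imbalanced: float = 0.05
    frac_condition_specific: float = 0.5
    effect_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (self.mean_depth > 0 and self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("mean depth and shape parameters must be positive")
        for name in ("frac_imbalanced", "frac_condition_specific"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_variants < 1 or self.n_samples_per_condition < 1:
            raise ValueError("counts must be >= 1")


def simulate_allele_counts(spec: ImbalanceSimSpec
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant, per-sample, per-condition allele counts.

    Depth ~ Poisson(mean_depth); ref | depth ~ BetaBinomial with the
    null mean ref fraction alpha0/(alpha0+beta0) for null variants and
    a logit-shift of ``effect_shift`` for imbalanced ones (total
    concentration alpha0+beta0 preserved). Condition-specific variants
    carry the shift in exactly one condition. Returns ``(records,
    truth)``.
    """
    rng = _rng(spec.seed)
    n = spec.n_variants
    conc = spec.alpha0 + spec.beta0
    p_null = spec.alpha0 / conc
    p_shift = float(expit(logit(p_null) + spec.effect_shift))

    imbalanced = rng.random(n) < spec.frac_imbalanced
    cond_specific = imbalanced & (rng.random(n) < spec.frac_condition_specific)
    effect_condition = np.where(
        rng.random(n) < 0.5, CONDITIONS[0], CONDITIONS[1])

    variant_ids = np.array([f"var{i:06d}" for i in range(n)])
    rows = []
    for s in range(spec.n_samples_per_condition):
        sample = f"sample{s:02d}"
        for cond in CONDITIONS:
            active = imbalanced & (~cond_specific | (effect_condition == cond))
            p = np.where(active, p_shift, p_null)
            depth = rng.poisson(spec.mean_depth, size=n)
            frac = rng.beta(p * conc, (1 - p) * conc, size=n)
            ref = rng.binomial(depth, frac)
            rows.append(pd.DataFrame({
                "variant_id": variant_ids,
                "chrom": "chr1",
                "pos": np.arange(1, n + 1) * 1000,
                "sample_id": sample,
                "condition": cond,
                "ref_count": ref,
                "alt_count": depth - ref,
            }))
    records = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({
        "variant_id": variant_ids,
        "imbalanced": imbalanced,
        "condition_specific": cond_specific,
        "effect_condition": np.where(
            cond_specific, effect_condition,
            np.where(imbalanced, "both", "none")),
    })
    return records, truth


# -------------------------------------------------------------- locus stats

@dataclass(frozen=True)
class LocusSimSpec:
    n_variants: int = 100
    block_size: int = 10
    within_block_r: float = 0.5
    causal_index: int | None = None
    ncp: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_eff: float = 50_000.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within-block correlation must lie in [0, 1)")
        if self.causal_index is not None and not (
                0 <= self.causal_index < self.n_variants):
            raise ValueError("causal_index out of range")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.n_eff <= 0 or self.block_size < 1:
            raise ValueError("n_eff and block_size must be positive")


def _block_of(i: int, block_size: int) -> int:
    return i // block_size


def simulate_locus_stats(spec: LocusSimSpec) -> pd.DataFrame:
    """Summary statistics with block-constant LD and a planted causal.

    z ~ MVN(R @ lam, R) with R block-diagonal (constant off-diagonal
    ``within_block_r`` inside blocks of ``block_size``) and lam carrying
    ``ncp`` at the causal variant; se = 1/sqrt(2 n_eff maf (1-maf)),
    beta = z * se; ``r2_to_index`` is the model r^2 to the causal
    (within_block_r^2 inside the causal's block, 0 elsewhere).
    """
    rng = _rng(spec.seed)
    n, r = spec.n_variants, spec.within_block_r
    block = np.arange(n) // spec.block_size
    # z_i = sqrt(r) g_block + sqrt(1-r) e_i has the block-constant correlation
    g = rng.standard_normal(block.max() + 1)
    e = rng.standard_normal(n)
    z = np.sqrt(r) * g[block] + np.sqrt(1 - r) * e

    mean = np.zeros(n)
    r2 = np.zeros(n)
    if spec.causal_index is not None:
        c = spec.causal_index
        same = block == block[c]
        mean[same] = r * spec.ncp          # (R lam)_i = r * ncp for neighbors
        mean[c] = spec.ncp
        r2[same] = r ** 2
        r2[c] = 1.0
    z = z + mean

    maf = rng.uniform(*spec.maf_range, size=n)
    se = 1.0 / np.sqrt(2.0 * spec.n_eff * maf * (1.0 - maf))
    return pd.DataFrame({
        "variant_id": [f"rs{i:06d}" for i in range(n)],
        "chrom": "chr1",
        "pos": np.arange(1, n + 1) * 1000,
        "beta": z * se,
        "se": se,
        "maf": maf,
        "r2_to_index": r2,
        "z": z,
    })


def simulate_coloc_pair(spec1: LocusSimSpec, spec2: LocusSimSpec,
                        shared: bool) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two traits on one variant grid, sharing (or not) the causal variant.

    With ``shared`` the second trait is forced onto the first trait's
    causal index; otherwise the causal indices must differ (one trait
    may be null). Noise is independent between traits (distinct seeds).
    """
    if spec1.n_variants != spec2.n_variants:
        raise ValueError("traits must share the variant grid")
    if shared:
        spec2 = dataclasses.replace(spec2, causal_index=spec1.causal_index)
    elif (spec1.causal_index is not None
          and spec1.causal_index == spec2.causal_index):
        raise ValueError("distinct causal variants requested but indices match")
    return simulate_locus_stats(spec1), simulate_locus_stats(spec2)


# -------------------------------------------------------- annotated genome

@dataclass(frozen=True)
class EnrichmentSimSpec:
    n_windows: int = 500
    variants_per_window: int = 50
    pi: float = 0.2
    gamma: float = 0.0
    frac_annotated: float = 0.1
    ncp: float = 6.0
    n_eff: float = 50_000.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pi < 1:
            raise ValueError("pi must lie in (0, 1)")
        if not 0 < self.frac_annotated < 1:
            raise ValueError("frac_annotated must lie in (0, 1)")
        if self.n_windows < 1 or self.variants_per_window < 1:
            raise ValueError("counts must be >= 1")


def simulate_annotated_genome(spec: EnrichmentSimSpec
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed summary statistics with annotation-enriched causals.

    Each 1 Mb window independently harbors an association with
    probability ``pi``; the causal variant within an associated window
    is drawn with probability proportional to exp(gamma * a_i), where
    a_i ~ Bernoulli(frac_annotated); causal z-scores are N(ncp, 1),
    others N(0, 1). Returns ``(stats, truth)`` where ``stats`` carries
    ``variant_id, chrom, pos, beta, se, maf, z, annotated`` (positions
    place window k inside [k Mb, (k+1) Mb)) and ``truth`` records the
    per-window association flag and causal variant.
    """
    rng = _rng(spec.seed)
    nw, m = spec.n_windows, spec.variants_per_window
    total = nw * m
    a = rng.random(total) < spec.frac_annotated
    associated = rng.random(nw) < spec.pi

    causal = np.zeros(total, dtype=bool)
    weights = np.exp(spec.gamma * a.astype(float)).reshape(nw, m)
    picks = np.array([rng.choice(m, p=w / w.sum()) for w in weights])
    for k in np.flatnonzero(associated):
        causal[k * m + picks[k]] = True

    z = rng.standard_normal(total) + spec.ncp * causal
    maf = rng.uniform(0.1, 0.5, size=total)
    se = 1.0 / np.sqrt(2.0 * spec.n_eff * maf * (1.0 - maf))
    window = np.repeat(np.arange(nw), m)
    offset = np.tile((np.arange(m) + 1) * (1_000_000 // (m + 1)), nw)
    stats = pd.DataFrame({
        "variant_id": [f"ev{i:06d}" for i in range(total)],
        "chrom": "chr1",
        "pos": window * 1_000_000 + offset,
        "beta": z * se,
        "se": se,
        "maf": maf,
        "z": z,
        "annotated": a,
    })
    truth = pd.DataFrame({
        "window": np.arange(nw),
        "associated": associated,
        "causal_variant": np.where(
            associated, [f"ev{k * m + picks[k]:06d}" for k in range(nw)], ""),
    })
    return stats, truth


def annotation_bed(stats: pd.DataFrame, half_width: int = 100) -> pd.DataFrame:
    """BED-style intervals covering the annotated variants of a simulated
    genome (for exercising the interval-overlap path end to end)."""
    ann = stats.loc[stats["annotated"]]
    return pd.DataFrame({
        "chrom": ann["chrom"].to_numpy(),
        "start": np.maximum(ann["pos"].to_numpy() - 1 - half_width, 0),
        "end": ann["pos"].to_numpy() + half_width,
    })


# ------------------------------------------------------------- intervals

def simulate_intervals(n_a: int, n_b: int, genome_length: int,
                       attraction: float = 0.0, seed: int = 0,
                       width: int = 500
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two interval sets with tunable attraction of A toward B.

    B midpoints are uniform on the genome; A midpoints are uniform when
    ``attraction`` is 0 and otherwise displaced a fraction
    attraction/(1+attraction) of the way toward the nearest B midpoint
    (attraction -> inf collapses A onto B). Fixed interval width; both
    sets are returned coordinate-sorted with non-negative coordinates.
    """
    if genome_length <= width:
        raise ValueError("genome too short for the interval width")
    if attraction < 0:
        raise ValueError("attraction must be >= 0")
    rng = _rng(seed)
    half = width // 2
    lo, hi = half, genome_length - half

    b_mid = np.sort(rng.uniform(lo, hi, size=n_b))
    a_mid = rng.uniform(lo, hi, size=n_a)
    if attraction > 0 and n_b > 0:
        j = np.clip(np.searchsorted(b_mid, a_mid), 0, n_b - 1)
        j_prev = np.maximum(j - 1, 0)
        nearest = np.where(np.abs(b_mid[j] - a_mid) <= np.abs(a_mid - b_mid[j_prev]),
                           b_mid[j], b_mid[j_prev])
        f = attraction / (1.0 + attraction)
        a_mid = a_mid + f * (nearest - a_mid)
    a_mid = np.sort(a_mid)

    def _frame(mid):
        start = np.maximum(np.round(mid).astype(np.int64) - half, 0)
        return pd.DataFrame({"chrom": "chr1", "start": start,
                             "end": start + width})

    return _frame(a_mid), _frame(b_mid)


# -------------------------------------------------------------- reporter

@dataclass(frozen=True)
class ReporterSimSpec:
    n_wells_per_group: int = 8
    allele_effect: float = 0.0        # log2 fold, alt vs ref
    treatment_interaction: float = 0.0  # extra log2 allelic difference, treated
    batch_sd: float = 0.25
    noise_sd: float = 0.25
    n_batches: int = 2
    baseline: float = 2.0             # log2 activity of constructs over empty
    treatment_effect: float = 0.5     # log2 main effect of treatment
    seed: int = 0

    def __post_init__(self):
        if self.batch_sd < 0 or self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive, batch_sd non-negative")
        if self.n_wells_per_group < 1 or self.n_batches < 1:
            raise ValueError("counts must be >= 1")


def simulate_reporter(spec: ReporterSimSpec) -> pd.DataFrame:
    """Dual-luciferase wells for ref/alt x treated/untreated plus empties.

    log2(firefly/renilla) = baseline + allele effect (alt) + treatment
    main effect + interaction (alt x treated) + batch offset + noise;
    empty-vector wells (per batch and treatment) carry only batch
    offset and noise. Renilla is a constant reference signal.
    """
    rng = _rng(spec.seed)
    batch_offsets = (rng.normal(0.0, spec.batch_sd, size=spec.n_batches)
                     if spec.batch_sd > 0 else np.zeros(spec.n_batches))
    rows = []

    def _add(construct, treatment, batch, mu):
        log2_ratio = mu + batch_offsets[batch] + rng.normal(0, spec.noise_sd)
        renilla = 100.0
        rows.append({"construct": construct, "treatment": treatment,
                     "batch": f"batch{batch}",
                     "firefly": renilla * 2.0 ** log2_ratio,
                     "renilla": renilla})

    for construct in ("ref", "alt"):
        for treatment in CONDITIONS:
            for w in range(spec.n_wells_per_group):
                mu = spec.baseline
                if treatment == "treated":
                    mu += spec.treatment_effect
                if construct == "alt":
                    mu += spec.allele_effect
                    if treatment == "treated":
                        mu += spec.treatment_interaction
                _add(construct, treatment, w % spec.n_batches, mu)
    for treatment in CONDITIONS:
        for batch in range(spec.n_batches):
            for _ in range(2):       # duplicate empty wells per batch
                _add("empty", treatment, batch, 0.0)
    return pd.DataFrame(rows, columns=WELL_COLUMNS_ORDER)


WELL_COLUMNS_ORDER = ["construct", "treatment", "batch", "firefly", "renilla"]
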