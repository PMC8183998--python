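# Methods

`cisreg` implements the statistical chain used to connect
condition-dependent regulatory chromatin to genetic disease risk:
allelic imbalance in chromatin accessibility at heterozygous SNPs,
Bayesian fine-mapping with credible sets, colocalization of two
association signals, annotation enrichment of GWAS signals, interval
proximity statistics, and allele-specific reporter-assay tests. This
note documents the models, their assumptions, the defaults, and what
the synthetic-data generators do and do not emulate.

## Allelic imbalance

**Model.** At a heterozygous SNP, reads covering the variant are
classified by allele. Under the null of no cis-regulatory effect the
reference-allele count at total depth *n* follows a beta-binomial,
`ref ~ BetaBinomial(n, α, β)`, whose mean ref fraction `α/(α+β)` is
close to 0.5 (residual reference-mapping bias can shift it slightly)
and whose intraclass-correlation overdispersion is

    ρ = 1 / (α + β + 1).

ρ → 0 recovers the binomial; typical chromatin-accessibility data have
ρ on the order of 0.01.

**Filtering and merging.** A variant is retained for a sample only
when that sample has depth ≥ 10 in both the treated and untreated
condition and each allele is seen ≥ 3 times summed over the sample's
two conditions; retained per-sample counts are summed across samples
within each condition. Both thresholds are parameters
(`min_depth`, `min_allele_obs`).

**Fitting.** (α, β) are estimated by maximum likelihood over all
merged variants of a condition, optimized in log-shape space
(L-BFGS-B, method-of-moments start, `ftol` 1e-10). The fit uses all
variants, not a pre-selected null subset: when the large majority of
variants are null the ML fit is dominated by the null component and
behaves like an empirical-null fit. This assumption matters — if a
large fraction of variants carries strong imbalance, the fitted ρ
inflates and the test loses power (visible in the test suite's scan
test, which uses a 3% non-null fraction).

**Testing.** The imbalance test is exact and two-sided with
minimum-likelihood ordering: p is the total null probability of all
outcomes k ∈ {0..n} whose pmf does not exceed the pmf of the observed
count (ties included via a 1e-10 relative tolerance). Being discrete,
the test is conservative: its type-I error at nominal 0.05 sits near
0.04 at depth ≈ 50. Multiple testing is handled with Benjamini–
Hochberg adjusted p-values ("q-values" in the output), significant at
FDR < 0.10 by default.

**Cross-condition heterogeneity.** For variants imbalanced in either
condition and observed in both, the 2×2 (allele × condition) table is
tested with Pearson's chi-squared with Yates continuity correction
(|O−E| reduced by 0.5 and floored at 0, df = 1) — the behaviour of R's
`prop.test`. The correction makes the test conservative at moderate
depth.

## Fine-mapping

Per-variant evidence is the Wakefield approximate Bayes factor. With
`V = se²`, `z = beta/se` and a normal effect prior of variance `W`:

    log ABF = ½ ln(V/(V+W)) + z²/2 · W/(V+W).

`W` defaults to 0.04 (prior sd 0.2 per allele) and is exposed
everywhere as `prior_variance`. All ABF arithmetic is in log space;
posteriors are softmax/log-sum-exp, so genome-wide-significant z-scores
cannot overflow.

A locus is the variants on the index chromosome within a window of
total width 5 Mb centred on the index ("within a 5 Mb window" is read
as ±2.5 Mb; configurable) that are in at least low LD with the index
(r² > 0.1, strict). r² values are inputs — the package computes no LD.
Variants are pre-filtered to MAF > 0.05 (strict). Under a
single-causal-variant assumption, PPA_i = ABF_i / Σ_j ABF_j (no null
term in the denominator), and the 99% credible set is the shortest
descending-PPA prefix whose cumulative mass reaches 0.99; the variant
that crosses the level is included, and PPA ties break by variant id
for determinism.

## Colocalization

Two traits on an identical variant grid are compared under five
hypotheses (H0 none, H1/H2 one trait only, H3 two distinct causal
variants, H4 one shared causal variant) with per-variant priors
p1 = p2 = 1e-4 and p12 = 1e-5 (the standard defaults of this model
class; configurable). With L1 = Σ BF1, L2 = Σ BF2, S = Σ BF1·BF2 the
unnormalized weights are 1, p1·L1, p2·L2, p1·p2·(L1·L2 − S), p12·S,
normalized to PP0..PP4. The H3 difference is evaluated by signed
log-sum-exp; if cancellation drives it non-positive it is clamped to
zero with a warning (for a single-variant grid the clamp is exact).
Signals are called colocalized when PP4 > 0.80, strict.

## Annotation enrichment

A deliberately simple hierarchical window model for one binary
annotation. The genome is partitioned into 1 Mb windows
(index `floor((pos−1)/window_size)` per chromosome). Window k harbors
at most one association, with probability Π; given an association,
variant i in the window is causal with probability
`w_i ∝ exp(γ·a_i)`, a softmax over the window; the marginal likelihood
is `Π_k [(1−Π) + Π Σ_i w_i ABF_i]`. γ is the natural-log enrichment of
the annotation among causal variants. (γ, Π) are maximized jointly
(Π on the logit scale, L-BFGS-B, with a 20-point γ-grid profile
restart on failure), and the 95% CI on γ is the profile-likelihood
interval at the χ²₁ cutoff (log-likelihood drop 1.9207), located by
bracketing and Brent root-finding (tolerance 1e-4 on γ).

Degenerate cases are reported, not papered over: a globally constant
annotation raises an identifiability error, and a likelihood that is
flat in γ across the search range (e.g. all ABFs equal) returns a fit
flagged `degenerate` with an infinite CI. This model intentionally
omits multi-annotation joint fits, penalization and cross-validation;
it supplies exactly a log-enrichment estimate with a 95% CI.

## Interval proximity

Intervals are BED-convention 0-based half-open; strand is ignored.

* **Canonical peak merge.** Peaks pooled across conditions are sorted
  by ascending significance value (smaller = more significant) and
  accepted greedily iff they overlap no already-accepted peak, which
  generalizes "keep the more significant of two overlapping peaks" to
  overlap chains deterministically.
* **Proximity.** A site is proximal to a gene set when the gap between
  the site and any gene-body interval is ≤ 100 kb; overlap or abutment
  is gap 0. Gene bodies (not TSSs) anchor the distance. The
  {differential, background} × {proximal, not} table gets a two-sided
  Fisher exact test; the odds ratio is the unconditioned (a·d)/(b·c)
  with 0-cells reported as 0/inf/nan rather than continuity-corrected.
* **Relative distance.** For each query midpoint, d = distance to the
  nearer flanking reference midpoint divided by the flanking span,
  d ∈ [0, 0.5], uniform under independent placement. Query midpoints
  outside the reference span, or on chromosomes with fewer than two
  reference intervals, are skipped with a warning. The distribution
  matches `bedtools reldist` (cross-checked in the test suite).
* **Distribution comparison** uses the two-sample two-sided
  Kolmogorov–Smirnov test with asymptotic p.
* **TF-binding overlap** uses ≥ 1 bp intersection (abutting half-open
  intervals do not overlap), a Fisher test and fold-enrichment =
  ratio of overlap rates, with an explicit infinity when the
  background rate is zero.

## Reporter assays

Per well, firefly is normalized to renilla; fold change divides that
ratio by the mean empty-vector ratio of the same treatment. Batch
effects are removed by centering log2 folds per batch and restoring
the grand mean — exactly the identity for a single batch, and an
operation that preserves within-batch contrasts. Allelic effects per
treatment use a two-sided Welch (unequal-variance) t-test on log2
folds; allelic ratios are reported as ratios of geometric means with a
Welch–Satterthwaite 95% CI on the log2 difference.

The treatment dependence of the allelic ratio is tested by
permutation: the statistic is T = |log ratio-of-ratios| of group mean
folds, allele labels are permuted within each treatment stratum
independently (preserving the treatment structure so that exactly the
treatment × allele interaction is tested), and p uses the add-one
estimator (1 + #{T* ≥ T}) / (1 + n_perm), which is never below
1/(1+n_perm). Default n_perm = 100,000.

## Synthetic data

Every pipeline input has a seeded generator; each is a pure function
of its spec (same seed ⇒ byte-identical output) and returns the
planted truth alongside the data. Ground truth never feeds the
analysis modules outside tests.

* **Allele counts.** Depth per variant × sample × condition is
  Poisson (default mean 50, seven samples per condition) — the
  simplest overdispersion-free depth model, so all count
  overdispersion is attributable to the beta-binomial. Ref counts are
  beta-binomial with shapes α₀ = 40.78, β₀ = 39.26 (ρ ≈ 0.012, the
  regime of real accessibility data); imbalanced variants shift the
  mean ref fraction on the logit scale at fixed concentration, in one
  condition for condition-specific variants. The beta draw is
  independent per sample and condition, so merged counts are less
  overdispersed than per-sample counts; parameter-recovery tests
  therefore fit per-sample-level counts.
* **Locus summary statistics.** LD is block-constant: z-scores are
  MVN with correlation r inside blocks of 10 variants (drawn as
  `√r·g_block + √(1−r)·e_i`), mean `ncp` at the causal variant and
  `r·ncp` for its block-mates. se = 1/√(2·n_eff·maf(1−maf)) with
  n_eff = 50,000 and maf ~ U(0.1, 0.5); beta = z·se; `r2_to_index` is
  the model r². This preserves exactly the r²-thresholding and
  PPA-ranking behaviour under test while staying analytically
  tractable; it does not emulate realistic LD decay.
* **Coloc pairs** reuse the locus generator with the causal index
  forced equal (shared) or required distinct, and independent noise.
* **Annotated genome.** Per 1 Mb window: association with probability
  Π; causal variant chosen ∝ exp(γ·a_i) with a_i ~ Bern(0.1); causal
  z ~ N(ncp, 1) with ncp = 6 (a strong but sub-extreme GWAS signal),
  null z ~ N(0, 1). The spec carries `ncp` and `n_eff` so the z-scores
  convert to (beta, se) on the scale the ABF machinery expects.
* **Intervals.** Reference midpoints uniform; query midpoints uniform,
  then displaced a fraction attraction/(1+attraction) of the way
  toward the nearest reference midpoint, so attraction 0 is exactly
  uniform and attraction → ∞ collapses onto the references. Interval
  width is fixed at 500 bp.
* **Reporter wells.** log2(firefly/renilla) = baseline 2 (constructs
  over empty) + treatment main effect 0.5 + allele effect (alt) +
  interaction (alt × treated) + batch offset ~ N(0, 0.25) + noise
  ~ N(0, 0.25), eight wells per group over two batches with duplicate
  empty wells per batch × treatment — the scale of a typical
  48-well dual-luciferase experiment.

**What passing tests show.** The generators reproduce the statistical
structure the methods assume (beta-binomial counts, block LD,
softmax-enriched causals, uniform or attracted intervals, log-normal
well noise). They do not emulate mapping bias, LD decay, allele
frequency spectra, batch × treatment confounding, or plate-position
effects, so calibration and recovery results here demonstrate
correctness of the statistics, not robustness to every artefact of
real data.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds carried
in the sim specs and config. The test suite and demo pipeline use
deliberately modest sizes — e.g. 10,000 variants for calibration,
5,000 for ρ recovery, 50 seeds × (500 windows × 50 variants) for
enrichment CI coverage, 100 seeds for fine-mapping rank recovery,
100,000 permutations where the permutation test itself is under
test and 2,000–5,000 elsewhere — chosen so the whole suite completes
in a few minutes while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

* Single-causal-variant assumptions throughout fine-mapping and
  colocalization; no conditional or multi-signal analysis.
* The enrichment model handles one binary annotation; its "≤ 1
  association per window" simplification undercounts windows with
  multiple independent signals.
* BH q-values are used where a Storey-type estimator could be
  slightly more powerful.
* The heterogeneity test treats merged counts as independent
  binomials, ignoring the shared overdispersion structure.
* No read-level simulation or mapping-bias correction: allele counts
  are assumed to arrive already corrected.
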