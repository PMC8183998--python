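"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes imbalance -> heterogeneity, fine-mapping ->
credible set, colocalization, annotation enrichment, interval
proximity, and reporter statistics, either on user-supplied input
files or on a freshly simulated demo dataset, writing one TSV per
stage plus a JSON run manifest (config, seed, version, record counts).
Stage timings are emitted through the ``cisreg.pipeline`` logger;
``run.log`` and the manifest are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coloc, enrichment, finemap, imbalance, io, \
    proximity, reporter, synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def simulate_inputs(outdir: Path, seed: int) -> dict[str, Path]:
    """Write a complete demo dataset (all pipeline inputs) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    counts, truth = synthetic.simulate_allele_counts(
        synthetic.ImbalanceSimSpec(n_variants=1500, seed=seed))
    paths["counts"] = outdir / "allele_counts.tsv"
    io.write_tsv(counts, paths["counts"])
    io.write_tsv(truth, outdir / "allele_counts_truth.tsv")

    locus = synthetic.simulate_locus_stats(synthetic.LocusSimSpec(
        n_variants=200, block_size=10, within_block_r=0.5,
        causal_index=42, ncp=8.0, seed=seed + 1))
    paths["stats"] = outdir / "gwas_stats.tsv"
    io.write_tsv(locus, paths["stats"])

    t1, t2 = synthetic.simulate_coloc_pair(
        synthetic.LocusSimSpec(n_variants=200, block_size=10,
                               within_block_r=0.5, causal_index=42,
                               ncp=8.0, seed=seed + 2),
        synthetic.LocusSimSpec(n_variants=200, block_size=10,
                               within_block_r=0.5, causal_index=42,
                               ncp=8.0, seed=seed + 3),
        shared=True)
    paths["trait1"] = outdir / "trait1_stats.tsv"
    paths["trait2"] = outdir / "trait2_stats.tsv"
    io.write_tsv(t1, paths["trait1"])
    io.write_tsv(t2, paths["trait2"])

    genome, gtruth = synthetic.simulate_annotated_genome(
        synthetic.EnrichmentSimSpec(n_windows=300, variants_per_window=30,
                                    pi=0.2, gamma=2.0, frac_annotated=0.1,
                                    seed=seed + 4))
    paths["enrich_stats"] = outdir / "enrich_stats.tsv"
    io.write_tsv(genome.drop(columns=["annotated"]), paths["enrich_stats"])
    io.write_tsv(gtruth, outdir / "enrich_truth.tsv")
    paths["annotation"] = outdir / "annotation.bed"
    io.write_bed(synthetic.annotation_bed(genome), paths["annotation"])

    diff, genes = synthetic.simulate_intervals(
        n_a=400, n_b=300, genome_length=50_000_000, attraction=3.0,
        seed=seed + 5)
    nondiff, _ = synthetic.simulate_intervals(
        n_a=800, n_b=1, genome_length=50_000_000, attraction=0.0,
        seed=seed + 6)
    paths["diff_sites"] = outdir / "diff_sites.bed"
    paths["nondiff_sites"] = outdir / "nondiff_sites.bed"
    paths["genes"] = outdir / "genes.bed"
    io.write_bed(diff, paths["diff_sites"])
    io.write_bed(nondiff, paths["nondiff_sites"])
    io.write_bed(genes, paths["genes"])

    wells = synthetic.simulate_reporter(synthetic.ReporterSimSpec(
        allele_effect=0.5, treatment_interaction=1.0, seed=seed + 7))
    paths["wells"] = outdir / "reporter_wells.tsv"
    io.write_tsv(wells, paths["wells"])
    return paths


def run_pipeline(config: PipelineConfig, inputs: dict[str, Path] | None,
                 outdir, simulate: bool = False) -> Path:
    """Run every configured stage; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    counts_out: dict[str, int] = {}

    if simulate:
        inputs = simulate_inputs(outdir / "inputs", config.seed)
    if not inputs:
        raise ValueError("no inputs given and simulation not requested")

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (outdir / "run.log").write_text("\n".join(
                log_lines + [f"{name}\tFAILED\t{exc}"]) + "\n")
            raise StageError(name, exc) from exc
        logger.info("stage %s finished in %.3fs", name,
                    time.perf_counter() - t0)
        log_lines.append(f"{name}\tok")
        return result

    # ------------------------------------------------ allelic imbalance
    def _imbalance():
        if "counts" not in inputs:
            raise FileNotFoundError("allele-count table not provided")
        records = io.read_counts_tsv(inputs["counts"])
        merged = imbalance.filter_and_merge_counts(
            records, min_depth=config.min_depth,
            min_allele_obs=config.min_allele_obs)
        results, params = imbalance.imbalance_scan(merged)
        io.write_tsv(results, outdir / "imbalance.tsv")
        het = imbalance.heterogeneity_scan(results,
                                           fdr=config.imbalance_fdr)
        io.write_tsv(het, outdir / "heterogeneity.tsv")
        counts_out["imbalance_variants"] = int(results["variant_id"].nunique())
        counts_out["heterogeneity_tested"] = int(len(het))
        return {c: {"alpha": p.alpha, "beta": p.beta,
                    "overdispersion": p.overdispersion}
                for c, p in params.items()}

    fitted = _stage("imbalance", _imbalance)

    # ------------------------------------------------------ fine-mapping
    def _finemap():
        stats = io.read_stats_tsv(inputs["stats"])
        if "r2_to_index" not in stats.columns:
            raise ValueError("fine-mapping input needs an r2_to_index column")
        filtered = finemap.maf_filter(stats, config.maf_threshold)
        index_id = filtered.loc[
            (filtered["beta"] / filtered["se"]).abs().idxmax(), "variant_id"]
        locus, cs = finemap.fine_map(
            stats, index_id, window=config.locus_window,
            r2_min=config.r2_min, level=config.credible_level,
            maf_threshold=config.maf_threshold,
            prior_variance=config.prior_variance)
        io.write_tsv(locus, outdir / "finemap.tsv")
        counts_out["locus_variants"] = int(len(locus))
        counts_out["credible_set_size"] = int(len(cs.variant_ids))
        return {"index": str(index_id),
                "credible_set_size": len(cs.variant_ids),
                "top_ppa": max(cs.ppa)}

    fm = _stage("finemap", _finemap) if "stats" in inputs else None

    # ---------------------------------------------------- colocalization
    def _coloc():
        s1 = io.read_stats_tsv(inputs["trait1"])
        s2 = io.read_stats_tsv(inputs["trait2"])
        if not (s1["variant_id"].to_numpy() == s2["variant_id"].to_numpy()).all():
            raise ValueError("traits are not on the same variant grid")
        la1 = finemap.log_abf(s1["beta"].to_numpy(), s1["se"].to_numpy(),
                              config.prior_variance)
        la2 = finemap.log_abf(s2["beta"].to_numpy(), s2["se"].to_numpy(),
                              config.prior_variance)
        priors = coloc.ColocPriors(config.coloc_p1, config.coloc_p2,
                                   config.coloc_p12)
        res = coloc.colocalize(la1, la2, priors)
        row = {"pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
               "pp3": res.pp3, "pp4": res.pp4,
               "colocalized": coloc.is_colocalized(res, config.coloc_threshold)}
        io.write_tsv(pd.DataFrame([row]), outdir / "coloc.tsv")
        counts_out["coloc_variants"] = int(len(s1))
        return row

    cl = (_stage("coloc", _coloc)
          if "trait1" in inputs and "trait2" in inputs else None)

    # ------------------------------------------------------- enrichment
    def _enrich():
        stats = io.read_stats_tsv(inputs["enrich_stats"])
        annotation = io.read_bed(inputs["annotation"])
        fit = enrichment.enrichment_analysis(
            stats, annotation, window_size=config.enrichment_window,
            maf_threshold=config.maf_threshold,
            prior_variance=config.prior_variance)
        row = {"gamma_hat": fit.gamma_hat, "ci_lo": fit.ci_lo,
               "ci_hi": fit.ci_hi, "pi_hat": fit.pi_hat,
               "log_likelihood": fit.log_likelihood}
        io.write_tsv(pd.DataFrame([row]), outdir / "enrichment.tsv")
        counts_out["enrichment_variants"] = int(len(stats))
        return row

    en = (_stage("enrichment", _enrich)
          if "enrich_stats" in inputs and "annotation" in inputs else None)

    # -------------------------------------------------------- proximity
    def _proximity():
        diff = io.read_bed(inputs["diff_sites"])
        nondiff = io.read_bed(inputs["nondiff_sites"])
        genes = io.read_bed(inputs["genes"])
        fisher = proximity.proximity_fisher(diff, nondiff, genes,
                                            window=config.proximity_window)
        rd_diff = proximity.relative_distance(diff, genes)
        rd_back = proximity.relative_distance(nondiff, genes)
        ks_d, ks_p = proximity.ks_compare(rd_diff, rd_back)
        rows = [{"test": "proximity_fisher",
                 "statistic": fisher.odds_ratio, "p_value": fisher.p_value},
                {"test": "reldist_ks", "statistic": ks_d, "p_value": ks_p}]
        io.write_tsv(pd.DataFrame(rows), outdir / "proximity.tsv")
        counts_out["diff_sites"] = int(len(diff))
        return {"fisher_or": fisher.odds_ratio, "fisher_p": fisher.p_value,
                "ks_D": ks_d, "ks_p": ks_p}

    px = (_stage("proximity", _proximity)
          if {"diff_sites", "nondiff_sites", "genes"} <= set(inputs) else None)

    # --------------------------------------------------------- reporter
    def _reporter():
        wells = io.read_wells_tsv(inputs["wells"])
        res = reporter.reporter_analysis(wells, n_perm=config.n_perm,
                                         seed=config.seed)
        io.write_tsv(res.folds, outdir / "reporter_folds.tsv")
        summary = {
            "ttest_p_treated": res.ttest_p["treated"],
            "ttest_p_untreated": res.ttest_p["untreated"],
            "allelic_ratio_treated": res.allelic_ratio["treated"].ratio,
            "allelic_ratio_untreated": res.allelic_ratio["untreated"].ratio,
            "ratio_of_ratios": res.ratio_of_ratios,
            "permutation_p": res.permutation_p,
            "n_perm": res.n_perm,
        }
        (outdir / "reporter_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        counts_out["reporter_wells"] = int(len(wells))
        return summary

    rp = _stage("reporter", _reporter) if "wells" in inputs else None

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "record_counts": counts_out,
        "stages": {
            "imbalance": fitted, "finemap": fm, "coloc": cl,
            "enrichment": en, "proximity": px, "reporter": rp,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
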