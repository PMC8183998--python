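"""Synthetic-data generators: determinism, null behaviour, and agreement
with closed-form moments of the planted models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cisreg import synthetic
from cisreg.synthetic import (EnrichmentSimSpec, ImbalanceSimSpec,
                              LocusSimSpec, ReporterSimSpec,
                              simulate_allele_counts,
                              simulate_annotated_genome, simulate_coloc_pair,
                              simulate_intervals, simulate_locus_stats,
                              simulate_reporter)


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [
        dict(mean_depth=0.0), dict(alpha0=-1.0), dict(frac_imbalanced=1.5),
    ])
    def test_imbalance_spec(self, bad):
        with pytest.raises(ValueError):
            ImbalanceSimSpec(**bad)

    @pytest.mark.parametrize("bad", [
        dict(within_block_r=1.0), dict(causal_index=100, n_variants=100),
        dict(maf_range=(0.0, 0.5)), dict(n_eff=-1),
    ])
    def test_locus_spec(self, bad):
        with pytest.raises(ValueError):
            LocusSimSpec(**bad)

    @pytest.mark.parametrize("bad", [
        dict(pi=0.0), dict(frac_annotated=1.0),
    ])
    def test_enrichment_spec(self, bad):
        with pytest.raises(ValueError):
            EnrichmentSimSpec(**bad)

    def test_reporter_spec(self):
        with pytest.raises(ValueError):
            ReporterSimSpec(noise_sd=0.0)
        with pytest.raises(ValueError):
            ReporterSimSpec(n_wells_per_group=0)


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        for maker in (
            lambda s: simulate_allele_counts(ImbalanceSimSpec(
                n_variants=50, seed=s))[0],
            lambda s: simulate_locus_stats(LocusSimSpec(
                n_variants=50, causal_index=3, ncp=5, seed=s)),
            lambda s: simulate_annotated_genome(EnrichmentSimSpec(
                n_windows=20, variants_per_window=5, seed=s))[0],
            lambda s: simulate_intervals(50, 30, 1_000_000, 1.0, seed=s)[0],
            lambda s: simulate_reporter(ReporterSimSpec(seed=s)),
        ):
            pd.testing.assert_frame_equal(maker(7), maker(7))
            assert not maker(7).equals(maker(8))


class TestAlleleCounts:
    def test_null_pooled_fraction_near_half(self):
        rec, _ = simulate_allele_counts(ImbalanceSimSpec(
            n_variants=2000, frac_imbalanced=0.0, alpha0=40.0, beta0=40.0,
            seed=0))
        pooled = rec["ref_count"].sum() / (rec["ref_count"]
                                           + rec["alt_count"]).sum()
        assert pooled == pytest.approx(0.5, abs=0.01)

    def test_zero_shift_indistinguishable(self):
        rec, truth = simulate_allele_counts(ImbalanceSimSpec(
            n_variants=2000, frac_imbalanced=0.3, effect_shift=0.0, seed=1))
        merged = rec.groupby("variant_id")[["ref_count", "alt_count"]].sum()
        frac = merged["ref_count"] / (merged["ref_count"]
                                      + merged["alt_count"])
        imb = truth.set_index("variant_id")["imbalanced"]
        from scipy.stats import ks_2samp
        p = ks_2samp(frac[imb], frac[~imb]).pvalue
        assert p > 0.01

    def test_variance_matches_beta_binomial_closed_form(self):
        """Empirical ref-count variance matches the beta-binomial (not
        binomial) law compounded over the Poisson depth.

        With depth N ~ Poisson(lam) and ref | N ~ BetaBinomial(N, a, b):
        Var = p(1-p) (lam + rho lam^2) + p^2 lam, versus the binomial
        analogue p(1-p) lam + p^2 lam.
        """
        spec = ImbalanceSimSpec(n_variants=2000, frac_imbalanced=0.0,
                                alpha0=40.78, beta0=39.26, mean_depth=50,
                                n_samples_per_condition=3, seed=1)
        rec, _ = simulate_allele_counts(spec)
        p = spec.alpha0 / (spec.alpha0 + spec.beta0)
        rho = 1 / (spec.alpha0 + spec.beta0 + 1)
        lam = spec.mean_depth
        bb_var = p * (1 - p) * (lam + rho * lam ** 2) + p ** 2 * lam
        binom_var = p * (1 - p) * lam + p ** 2 * lam
        emp = rec["ref_count"].var()
        assert emp > binom_var
        assert emp == pytest.approx(bb_var, rel=0.10)

    def test_condition_specific_shift_in_one_condition(self):
        rec, truth = simulate_allele_counts(ImbalanceSimSpec(
            n_variants=500, frac_imbalanced=0.3, frac_condition_specific=1.0,
            effect_shift=2.0, seed=2))
        merged = rec.groupby(["variant_id", "condition"])[
            ["ref_count", "alt_count"]].sum().reset_index()
        merged["frac"] = merged["ref_count"] / (merged["ref_count"]
                                                + merged["alt_count"])
        t = truth[truth["condition_specific"]].iloc[0]
        both = merged[merged["variant_id"] == t["variant_id"]]
        shifted = both[both["condition"] == t["effect_condition"]]
        other = both[both["condition"] != t["effect_condition"]]
        assert shifted["frac"].iloc[0] > 0.65
        assert abs(other["frac"].iloc[0] - 0.5) < 0.15


class TestLocusStats:
    def test_null_z_standard_normal(self):
        df = simulate_locus_stats(LocusSimSpec(
            n_variants=10_000, block_size=10, within_block_r=0.3,
            causal_index=None, seed=3))
        assert df["z"].mean() == pytest.approx(0.0, abs=0.05)
        assert df["z"].var() == pytest.approx(1.0, abs=0.05)

    def test_neighbor_mean_is_r_times_ncp(self):
        """Monte-Carlo mean of a causal neighbour's z over 500 replicates
        approaches r * ncp."""
        zs = []
        for seed in range(500):
            df = simulate_locus_stats(LocusSimSpec(
                n_variants=20, block_size=10, within_block_r=0.5,
                causal_index=0, ncp=8.0, seed=seed))
            zs.append(df["z"].iloc[1])      # same block as the causal
        se = np.std(zs) / np.sqrt(len(zs))
        assert np.mean(zs) == pytest.approx(0.5 * 8.0, abs=4 * se + 0.05)

    def test_se_formula(self):
        df = simulate_locus_stats(LocusSimSpec(n_variants=10, seed=4))
        expected = 1 / np.sqrt(2 * 50_000 * df["maf"] * (1 - df["maf"]))
        np.testing.assert_allclose(df["se"], expected)

    def test_coloc_pair_grid_rules(self):
        s1 = LocusSimSpec(n_variants=50, causal_index=5, ncp=5, seed=0)
        s2 = LocusSimSpec(n_variants=50, causal_index=9, ncp=5, seed=1)
        t1, t2 = simulate_coloc_pair(s1, s2, shared=True)
        assert t2["r2_to_index"].idxmax() == 5   # forced onto trait 1's causal
        with pytest.raises(ValueError):
            simulate_coloc_pair(s1, LocusSimSpec(n_variants=40, seed=1),
                                shared=True)
        with pytest.raises(ValueError):
            simulate_coloc_pair(s1, LocusSimSpec(n_variants=50,
                                                 causal_index=5, seed=1),
                                shared=False)


class TestAnnotatedGenome:
    def test_no_enrichment_rate(self):
        g, truth = simulate_annotated_genome(EnrichmentSimSpec(
            n_windows=2000, variants_per_window=20, pi=0.5, gamma=0.0,
            frac_annotated=0.1, seed=5))
        causal_ids = set(truth.loc[truth["associated"], "causal_variant"])
        ann = g.set_index("variant_id")["annotated"]
        rate = np.mean([ann[v] for v in causal_ids])
        assert rate == pytest.approx(0.1, abs=0.03)

    def test_softmax_enrichment_rate(self):
        """gamma=2, 10% annotation: causals annotated at rate
        0.1 e^2 / (0.1 e^2 + 0.9) ~ 0.451 (many variants per window, so
        the within-window annotated fraction concentrates at 0.1)."""
        rates = []
        for seed in range(10):
            g, truth = simulate_annotated_genome(EnrichmentSimSpec(
                n_windows=500, variants_per_window=300, pi=0.5, gamma=2.0,
                frac_annotated=0.1, seed=seed))
            causal_ids = truth.loc[truth["associated"], "causal_variant"]
            ann = g.set_index("variant_id")["annotated"]
            rates.append(np.mean([ann[v] for v in causal_ids]))
        expected = 0.1 * np.e ** 2 / (0.1 * np.e ** 2 + 0.9)
        assert np.mean(rates) == pytest.approx(expected, abs=0.02)


class TestIntervals:
    def test_uniform_reldist(self):
        from cisreg.proximity import relative_distance
        a, b = simulate_intervals(10_000, 500, 200_000_000, attraction=0.0,
                                  seed=7)
        d = relative_distance(a, b)
        assert d.mean() == pytest.approx(0.25, abs=0.01)
        assert kstest(d * 2, "uniform").pvalue > 0.01

    def test_attraction_limit(self):
        from cisreg.proximity import relative_distance
        a, b = simulate_intervals(1000, 200, 50_000_000, attraction=1000.0,
                                  seed=8)
        d = relative_distance(a, b)
        assert np.median(d) < 0.01

    def test_sorted_nonnegative(self):
        a, b = simulate_intervals(100, 50, 1_000_000, 2.0, seed=9)
        for df in (a, b):
            assert (df["start"] >= 0).all()
            assert (df["start"] < df["end"]).all()
            assert df["start"].is_monotonic_increasing


class TestReporterWells:
    def test_every_batch_has_empties(self):
        wells = simulate_reporter(ReporterSimSpec(n_batches=3, seed=10))
        for batch, sub in wells.groupby("batch"):
            assert (sub["construct"] == "empty").sum() >= 2

    def test_zero_batch_sd_means_zero_offsets(self):
        a = simulate_reporter(ReporterSimSpec(batch_sd=1e-12, seed=11))
        assert set(a["construct"]) == {"ref", "alt", "empty"}

    def test_interaction_shifts_treated_ratio_only(self):
        wells = simulate_reporter(ReporterSimSpec(
            treatment_interaction=2.0, noise_sd=0.05, batch_sd=0.0001,
            n_wells_per_group=50, seed=12))
        lr = np.log2(wells["firefly"] / wells["renilla"])
        wells = wells.assign(lr=lr)
        g = wells.groupby(["construct", "treatment"])["lr"].mean()
        treated_diff = g["alt", "treated"] - g["ref", "treated"]
        untreated_diff = g["alt", "untreated"] - g["ref", "untreated"]
        assert treated_diff - untreated_diff == pytest.approx(2.0, abs=0.1)
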