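"""Generator invariants: HWE sampling, null ratios, determinism, truth record."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aeqtlmap.simulate import (
    CohortSpec,
    SimulationConfig,
    SimulationError,
    default_config,
    simulate,
    simulate_expression,
    simulate_haplotypes,
    simulate_mixing_series,
    single_gene_config,
)


def _cohort(name, n, freqs):
    return CohortSpec(name=name, n_individuals=n, haplotype_freqs=freqs,
                      ethnicity_probs={"white": 1.0})


class TestConfigValidation:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sum to 1"):
            SimulationConfig(
                snp_ids=["a"], haplotypes=["0", "1"],
                cohorts=[_cohort("X", 10, [0.6, 0.3])],
                genes={}, cis_effects={}, marker_sd={}, assay_bias={},
            )

    def test_empty_pool_rejected(self):
        with pytest.raises(SimulationError, match="empty"):
            SimulationConfig(
                snp_ids=["a"], haplotypes=[],
                cohorts=[], genes={}, cis_effects={}, marker_sd={}, assay_bias={},
            )

    def test_monomorphic_marker_flagged(self):
        with pytest.raises(SimulationError, match="monomorphic"):
            SimulationConfig(
                snp_ids=["s", "m"], haplotypes=["00", "10"],
                cohorts=[_cohort("X", 10, [0.5, 0.5])],
                genes={"G": ["m"]}, cis_effects={}, marker_sd={}, assay_bias={},
            )

    def test_negative_replicate_cv_rejected(self):
        with pytest.raises(SimulationError, match="replicate_cv"):
            single_gene_config(replicate_cv=-0.1)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = single_gene_config(n_individuals=20, seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.snp_ids == cfg.snp_ids
        assert back.cohorts[0].haplotype_freqs == pytest.approx(
            cfg.cohorts[0].haplotype_freqs
        )


class TestHaplotypes:
    def test_single_haplotype_everyone_homozygous(self):
        cfg = SimulationConfig(
            snp_ids=["a", "b"], haplotypes=["10"],
            cohorts=[_cohort("X", 30, [1.0])],
            genes={}, cis_effects={}, marker_sd={}, assay_bias={},
        )
        ds = simulate(cfg)
        assert (ds.genotypes.calls["a"] == 2).all()
        assert (ds.genotypes.calls["b"] == 0).all()

    def test_hwe_proportions_at_large_n(self):
        cfg = SimulationConfig(
            snp_ids=["a"], haplotypes=["0", "1"],
            cohorts=[_cohort("X", 10000, [0.5, 0.5])],
            genes={}, cis_effects={}, marker_sd={}, assay_bias={}, seed=13,
        )
        haps = simulate_haplotypes(cfg, "X")
        geno = haps.sum(axis=1)
        n = len(geno)
        for g, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            frac = (geno == g).mean()
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) < 3 * se

    def test_fixed_seed_reproducible(self):
        cfg = single_gene_config(n_individuals=50, seed=42)
        a = simulate(cfg)
        b = simulate(single_gene_config(n_individuals=50, seed=42))
        pd.testing.assert_frame_equal(a.genotypes.calls, b.genotypes.calls)
        pd.testing.assert_frame_equal(a.aer_measurements, b.aer_measurements)
        pd.testing.assert_frame_equal(a.ct, b.ct)

    def test_different_seed_differs(self):
        a = simulate(single_gene_config(n_individuals=50, seed=1))
        b = simulate(single_gene_config(n_individuals=50, seed=2))
        assert not a.genotypes.calls.equals(b.genotypes.calls)

    def test_genotype_hwe_chisquare_consistent(self):
        cfg = single_gene_config(n_individuals=2000, seed=3)
        ds = simulate(cfg)
        col = ds.genotypes.calls["snp1"].dropna()
        from aeqtlmap.io import hwe_chi2

        _, p = hwe_chi2(int((col == 0).sum()), int((col == 1).sum()),
                        int((col == 2).sum()))
        assert p > 1e-3  # simulated under HWE


class TestExpression:
    def test_null_model_ratios_exactly_one(self):
        cfg = single_gene_config(
            n_individuals=30, beta=0.0, marker_sd=0.0, replicate_cv=0.0,
            assay_bias=1.0, seed=4,
        )
        ds = simulate(cfg)
        cdna = ds.aer_measurements.query("template == 'cDNA'")
        assert np.allclose(cdna["ratio"], 1.0)

    def test_coupling_double_het_ratio_two(self):
        """beta = ln 2, noiseless: a coupling double heterozygote shows a
        cDNA ratio of exactly 2 at the transcribed marker."""
        cfg = SimulationConfig(
            snp_ids=["s", "m"], haplotypes=["11", "00"],
            cohorts=[_cohort("X", 20, [0.5, 0.5])],
            genes={"G": ["m"]}, cis_effects={"G": {"s": math.log(2)}},
            marker_sd={"m": 0.0}, assay_bias={"m": 1.0},
            replicate_cv=0.0, seed=6,
        )
        ds = simulate(cfg)
        het = ds.genotypes.calls.query("s == 1 and m == 1").index
        cdna = ds.aer_measurements.query(
            "template == 'cDNA' and individual_id in @het"
        )
        assert len(cdna) > 0
        assert np.allclose(cdna["ratio"], 2.0)

    def test_mean_log_ratio_matches_generative_beta(self):
        """Coupling pool, beta = ln 1.5: mean cDNA log ratio among double
        heterozygotes approaches the generative effect."""
        beta = math.log(1.5)
        cfg = SimulationConfig(
            snp_ids=["s", "m"], haplotypes=["11", "00"],
            cohorts=[_cohort("X", 500, [0.5, 0.5])],
            genes={"G": ["s", "m"][1:]}, cis_effects={"G": {"s": beta}},
            marker_sd={"m": 0.1}, assay_bias={"m": 1.0}, seed=8,
        )
        ds = simulate(cfg)
        het = ds.genotypes.calls.query("s == 1 and m == 1").index
        cdna = ds.aer_measurements.query(
            "template == 'cDNA' and individual_id in @het"
        )
        mean_log = np.log(cdna["ratio"]).mean()
        n = cdna["individual_id"].nunique()
        mc_se = 0.12 / math.sqrt(n)  # sigma_k + replicate noise
        assert abs(mean_log - beta) < 4 * mc_se

    def test_gdna_ratio_is_bias_times_noise(self):
        cfg = single_gene_config(
            n_individuals=30, assay_bias=1.4, replicate_cv=0.0, seed=9
        )
        ds = simulate(cfg)
        gdna = ds.aer_measurements.query("template == 'gDNA'")
        assert np.allclose(gdna["ratio"], 1.4)

    def test_haplotype_mismatch_rejected(self):
        cfg = single_gene_config(n_individuals=10)
        with pytest.raises(SimulationError):
            simulate_expression(np.zeros((5, 2), dtype=int), cfg, "SIM")


class TestTruthRecord:
    def test_analytic_truth_matches_monte_carlo(self):
        """The truth record's variances agree with a large re-simulation."""
        cfg = single_gene_config(
            n_individuals=4000, beta=math.log(2.0), dprime=0.0,
            marker_sd=0.1, trans_sd=0.5, seed=10,
        )
        ds = simulate(cfg)
        truth = ds.truth
        # empirical per-allele cis variance from the generative haplotypes
        beta = math.log(2.0)
        alleles = []
        for haps in truth["haplotypes"].values():
            for h in haps:
                alleles.append(beta * int(h[0]))
        v_emp = np.var(alleles)
        assert truth["cis_variance"]["GENE1"] == pytest.approx(v_emp, rel=0.1)
        # empirical total variance of measured log expression
        from aeqtlmap.io import delta_ct

        expr = delta_ct(ds.ct)
        v_tot_emp = expr["log_expr"].var(ddof=1)
        assert truth["total_variance"]["GENE1"] == pytest.approx(v_tot_emp, rel=0.1)
        frac = truth["cis_fraction"]["GENE1"]
        assert frac == pytest.approx(
            truth["cis_variance"]["GENE1"] / truth["total_variance"]["GENE1"]
        )

    def test_default_config_structure(self):
        cfg = default_config(seed=0)
        assert len(cfg.snp_ids) == 56
        assert sum(len(m) for m in cfg.genes.values()) == 6
        assert [c.n_individuals for c in cfg.cohorts] == [310, 177]
        for c in cfg.cohorts:
            assert sum(c.haplotype_freqs) == pytest.approx(1.0, abs=1e-9)


class TestMixingSeries:
    def test_single_level_unbiased(self):
        df = simulate_mixing_series("m", levels=[1.0], bias=1.0,
                                    replicate_cv=0.0, n_replicates=2)
        assert np.allclose(df["measured_ratio"], 1.0)

    def test_noiseless_multiplicative_bias(self):
        levels = [8, 4, 1, 0.25, 0.125]
        df = simulate_mixing_series("m", levels=levels, bias=1.2,
                                    replicate_cv=0.0)
        expected = np.repeat([1.2 * x for x in levels], 4)
        assert np.allclose(df["measured_ratio"], expected)

    def test_loglog_slope_is_one(self):
        df = simulate_mixing_series("m", bias=1.3, replicate_cv=0.05, seed=2)
        slope, *_ = stats.linregress(np.log(df["level"]),
                                     np.log(df["measured_ratio"]))[:5]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(SimulationError):
            simulate_mixing_series("m", levels=[1.0, 0.0])
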