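"""Phase indicators, mixture likelihood, MLE, LRT, scan and diagnostics."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aeqtlmap.io import GenotypeTable
from aeqtlmap.model import (
    IdentifiabilityError,
    ModelError,
    aer_loglik,
    build_design,
    build_phase_indicators,
    effect_to_fold,
    fit_mle,
    lrt,
    scan_snps,
    stratified_aer,
    top_snp,
)
from aeqtlmap.phasing import PhasePosterior, em_haplotype_freqs, phase_posteriors
from aeqtlmap.simulate import simulate, single_gene_config
from conftest import brute_force_mixture_loglik, normalize_dataset

LN2 = math.log(2.0)


def _posterior(configs, probs, snp_ids=("s", "m")):
    post = PhasePosterior(snp_ids=list(snp_ids))
    for ind, (cfg, pr) in enumerate(zip(configs, probs)):
        post.configs[ind] = cfg
        post.probs[ind] = np.asarray(pr, dtype=float)
    return post


def _aer(rows):
    return pd.DataFrame(rows, columns=["individual_id", "marker_id", "log_ratio"])


class TestPhaseIndicators:
    def test_homozygous_snp_gives_zero(self):
        post = _posterior(
            [[((0, 1), (0, 0)), ((0, 0), (0, 1))]], [[0.5, 0.5]]
        )
        ind = build_phase_indicators(post, ["s"], ["m"])
        for _, xs in ind[0]:
            assert xs["m"][0] == 0

    def test_coupling_and_repulsion_signs(self):
        # double het: coupling config (11 / 00) vs repulsion (10 / 01)
        post = _posterior(
            [[((1, 1), (0, 0)), ((1, 0), (0, 1))]], [[0.7, 0.3]]
        )
        ind = build_phase_indicators(post, ["s"], ["m"])
        (p1, xs1), (p2, xs2) = ind[0]
        assert xs1["m"][0] == 1   # coded allele on the numerator haplotype
        assert xs2["m"][0] == -1

    def test_orientation_flip_negates_x(self):
        post = _posterior([[((1, 1), (0, 0))]], [[1.0]])
        plus = build_phase_indicators(post, ["s"], ["m"], {"m": True})
        minus = build_phase_indicators(post, ["s"], ["m"], {"m": False})
        assert plus[0][0][1]["m"][0] == -minus[0][0][1]["m"][0]


class TestLoglik:
    def test_closed_form_two_observations(self):
        """Single marker, known phase, beta=0, sigma2=1, I = +-1."""
        post = _posterior(
            [[((1, 1), (0, 0))], [((1, 1), (0, 0))]], [[1.0], [1.0]],
        )
        design = build_design(
            _aer([[0, "m", 1.0], [1, "m", -1.0]]), post, ["s"], ["m"]
        )
        ll = aer_loglik(np.array([0.0]), np.array([1.0]), design)
        assert ll == pytest.approx(-math.log(2 * math.pi) - 1.0, abs=1e-12)
        assert ll == pytest.approx(-2.8379, abs=1e-4)

    def test_degenerate_posterior_equals_plain_normal(self):
        rng = np.random.default_rng(3)
        I = rng.normal(0.2, 0.5, size=8)
        post = _posterior(
            [[((1, 1), (0, 0))] for _ in I], [[1.0] for _ in I]
        )
        design = build_design(
            _aer([[j, "m", v] for j, v in enumerate(I)]), post, ["s"], ["m"]
        )
        beta, s2 = 0.3, 0.4
        expected = stats.norm.logpdf(I, loc=beta, scale=math.sqrt(s2)).sum()
        assert aer_loglik(np.array([beta]), np.array([s2]), design) == pytest.approx(
            expected, abs=1e-10
        )

    def test_matches_exhaustive_enumeration(self):
        """Mixture factorization agrees with brute-force joint enumeration."""
        configs = [
            [((1, 1), (0, 0)), ((1, 0), (0, 1))],
            [((1, 1), (0, 0)), ((1, 0), (0, 1))],
            [((0, 1), (0, 0))],
        ]
        probs = [[0.6, 0.4], [0.9, 0.1], [1.0]]
        post = _posterior(configs, probs)
        I = {0: 0.5, 1: -0.2, 2: 0.1}
        design = build_design(
            _aer([[j, "m", v] for j, v in I.items()]), post, ["s"], ["m"]
        )
        beta, s2 = 0.35, 0.2
        oracle = brute_force_mixture_loglik(
            [
                [
                    (pr, [(I[j], beta * (_x(cfg)), s2)])
                    for cfg, pr in zip(configs[j], probs[j])
                ]
                for j in range(3)
            ]
        )
        assert aer_loglik(np.array([beta]), np.array([s2]), design) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_zero_variance_rejected(self):
        post = _posterior([[((1, 1), (0, 0))]], [[1.0]])
        design = build_design(_aer([[0, "m", 0.1]]), post, ["s"], ["m"])
        with pytest.raises(ModelError):
            aer_loglik(np.array([0.0]), np.array([0.0]), design)

    def test_ratio_at_homozygous_marker_rejected(self):
        post = _posterior([[((0, 0), (0, 0))]], [[1.0]])
        with pytest.raises(ModelError, match="homozygous"):
            build_design(_aer([[0, "m", 0.1]]), post, ["s"], ["m"])


def _x(cfg):
    """Phase indicator of the single SNP for a (hap_a, hap_b) pair."""
    (s_a, m_a), (s_b, m_b) = cfg
    num, other = ((s_a, m_a), (s_b, m_b)) if m_a == 1 else ((s_b, m_b), (s_a, m_a))
    return num[0] - other[0]


class TestFit:
    def test_null_model_closed_form(self):
        rng = np.random.default_rng(5)
        I = rng.normal(0, 0.4, size=20)
        post = _posterior(
            [[((1, 1), (0, 0))] for _ in I], [[1.0] for _ in I]
        )
        design = build_design(
            _aer([[j, "m", v] for j, v in enumerate(I)]), post, ["s"], ["m"]
        )
        res = fit_mle(design.restrict([]))
        assert res.sigma2["m"] == pytest.approx(np.mean(I**2), rel=1e-12)

    def test_near_noiseless_recovery_of_ln2(self):
        """Coupling double-heterozygotes with I ~= ln 2 recover beta = ln 2."""
        rng = np.random.default_rng(6)
        I = LN2 + rng.normal(0, 1e-3, size=30)
        post = _posterior(
            [[((1, 1), (0, 0))] for _ in I], [[1.0] for _ in I]
        )
        design = build_design(
            _aer([[j, "m", v] for j, v in enumerate(I)]), post, ["s"], ["m"]
        )
        res = fit_mle(design)
        assert res.beta["s"] == pytest.approx(LN2, abs=5e-3)
        assert effect_to_fold(res.beta["s"]) == pytest.approx(2.0, abs=0.01)

    def test_monomorphic_snp_rejected(self):
        post = _posterior(
            [[((0, 1), (0, 0))], [((0, 0), (0, 1))]], [[1.0], [1.0]]
        )
        design = build_design(
            _aer([[0, "m", 0.2], [1, "m", -0.1]]), post, ["s"], ["m"]
        )
        with pytest.raises(IdentifiabilityError, match="'s'"):
            fit_mle(design)

    def test_individual_order_invariance(self, single_gene_dataset):
        cfg, ds, aer, _ = single_gene_dataset
        calls = ds.genotypes.calls.dropna()
        model = em_haplotype_freqs(calls, ["snp1", "marker1"])
        post = phase_posteriors(model, calls)
        d1 = build_design(aer, post, ["snp1"], ["marker1"])
        shuffled = aer.sample(frac=1.0, random_state=1).reset_index(drop=True)
        d2 = build_design(shuffled, post, ["snp1"], ["marker1"])
        r1, r2 = fit_mle(d1), fit_mle(d2)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-8)
        assert r1.beta["snp1"] == pytest.approx(r2.beta["snp1"], abs=1e-6)

    def test_orientation_flip_refit_equivalence(self, single_gene_dataset):
        """Flipping the marker's numerator allele (and thus I -> -I) leaves
        the fitted SNP effect unchanged."""
        cfg, ds, aer, _ = single_gene_dataset
        calls = ds.genotypes.calls.dropna()
        model = em_haplotype_freqs(calls, ["snp1", "marker1"])
        post = phase_posteriors(model, calls)
        d_plus = build_design(aer, post, ["snp1"], ["marker1"], {"marker1": True})
        flipped = aer.assign(log_ratio=-aer["log_ratio"])
        d_minus = build_design(flipped, post, ["snp1"], ["marker1"], {"marker1": False})
        r_plus, r_minus = fit_mle(d_plus), fit_mle(d_minus)
        assert r_plus.beta["snp1"] == pytest.approx(r_minus.beta["snp1"], abs=1e-6)
        assert r_plus.loglik == pytest.approx(r_minus.loglik, abs=1e-6)

    def test_marker_intercepts_absorb_residual_bias(self, single_gene_dataset):
        """Fitting un-normalized ratios with marker intercepts recovers the
        same SNP effect as fitting gDNA-normalized ratios without them."""
        cfg, ds, aer, _ = single_gene_dataset
        calls = ds.genotypes.calls.dropna()
        model = em_haplotype_freqs(calls, ["snp1", "marker1"])
        post = phase_posteriors(model, calls)
        from aeqtlmap.io import aggregate_replicates

        agg = aggregate_replicates(ds.aer_measurements)
        raw = agg[agg["template"] == "cDNA"].assign(
            log_ratio=lambda d: np.log(d["mean_ratio"])
        )
        d_raw = build_design(raw, post, ["snp1"], ["marker1"])
        d_norm = build_design(aer, post, ["snp1"], ["marker1"])
        with_int = fit_mle(d_raw, marker_intercepts=True)
        without = fit_mle(d_norm)
        # intercept estimates the log assay bias (1.2x in this scenario)
        assert with_int.alpha["marker1"] == pytest.approx(math.log(1.2), abs=0.05)
        # effects agree within sampling error of the extra free parameter
        se = 3 * float(with_int.beta_se["snp1"])
        assert with_int.beta["snp1"] == pytest.approx(without.beta["snp1"], abs=se)

    def test_lrt_rejects_mismatched_intercept_setting(self, single_gene_dataset):
        cfg, ds, aer, _ = single_gene_dataset
        calls = ds.genotypes.calls.dropna()
        model = em_haplotype_freqs(calls, ["snp1", "marker1"])
        post = phase_posteriors(model, calls)
        design = build_design(aer, post, ["snp1"], ["marker1"])
        full = fit_mle(design, marker_intercepts=True, compute_se=False)
        null = fit_mle(design.restrict([]))
        with pytest.raises(ModelError, match="intercept"):
            lrt(full, null)

    def test_phase_determined_data_equals_plain_likelihood(self, single_gene_dataset):
        """When every posterior is degenerate the mixture reduces to the
        ordinary normal likelihood computed independently."""
        cfg, ds, aer, _ = single_gene_dataset
        calls = ds.genotypes.calls.dropna()
        model = em_haplotype_freqs(calls, ["snp1", "marker1"])
        post = phase_posteriors(model, calls)
        forced = PhasePosterior(snp_ids=post.snp_ids)
        for ind in post.individuals():
            best = int(np.argmax(post.probs[ind]))
            forced.configs[ind] = [post.configs[ind][best]]
            forced.probs[ind] = np.array([1.0])
        design = build_design(aer, forced, ["snp1"], ["marker1"])
        beta, s2 = 0.4, 0.05
        mu = design.X[:, 0] * beta
        expected = stats.norm.logpdf(
            design.obs_I, loc=mu, scale=math.sqrt(s2)
        ).sum()
        got = aer_loglik(np.array([beta]), np.array([s2]), design)
        assert got == pytest.approx(expected, abs=1e-9)


class TestLRT:
    def test_identical_models(self, single_gene_dataset):
        cfg, ds, aer, _ = single_gene_dataset
        calls = ds.genotypes.calls.dropna()
        model = em_haplotype_freqs(calls, ["snp1", "marker1"])
        post = phase_posteriors(model, calls)
        design = build_design(aer, post, ["snp1"], ["marker1"])
        res = fit_mle(design)
        stat, df, p = lrt(res, res)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_survival_value(self):
        assert stats.chi2.sf(5.0, 1) == pytest.approx(0.02535, abs=1e-5)

    def test_mismatched_individuals_rejected(self):
        a = _fit_on(range(5))
        b = _fit_on(range(4))
        with pytest.raises(ModelError, match="individuals"):
            lrt(a, b)


def _fit_on(inds):
    rng = np.random.default_rng(1)
    post = _posterior(
        [[((1, 1), (0, 0))] for _ in inds], [[1.0] for _ in inds]
    )
    design = build_design(
        _aer([[j, "m", rng.normal()] for j in inds]), post, ["s"], ["m"]
    )
    return fit_mle(design.restrict([]))


class TestScan:
    def test_low_informative_snp_excluded(self):
        """Seven informative heterozygotes fall below the default cutoff."""
        rng = np.random.default_rng(8)
        n = 40
        snp = np.concatenate([np.ones(7), np.zeros(n - 7)])  # 7 hets only
        marker = np.ones(n)  # everyone het at the marker
        calls = pd.DataFrame({"snp1": snp, "marker1": marker}).astype(float)
        snps = pd.DataFrame(
            {"chrom": "9", "pos": [1, 2], "allele_a": "A", "allele_b": "G"},
            index=["snp1", "marker1"],
        )
        geno = GenotypeTable(calls=calls, snps=snps)
        aer = _aer([[j, "marker1", rng.normal(0, 0.2)] for j in range(n)])
        aer.columns = ["individual_id", "marker_id", "log_ratio"]
        scan = scan_snps(aer, geno, "G", ["marker1"], ["snp1"], m_tests=1)
        assert bool(scan["excluded"].iloc[0])
        assert scan["n_informative"].iloc[0] == 7
        assert "informative" in scan["reason"].iloc[0]
        lax = scan_snps(
            aer, geno, "G", ["marker1"], ["snp1"], m_tests=1, min_informative=1
        )
        assert not bool(lax["excluded"].iloc[0])

    def test_combined_markers_do_not_lose_informativity(self, two_cohort_small_config):
        ds = simulate(two_cohort_small_config)
        aer, _ = normalize_dataset(ds, {"m1": "G", "m2": "G"})
        both = scan_snps(ds.aer_measurements.pipe(lambda _: aer), ds.genotypes,
                         "G", ["m1", "m2"], ["s1"], m_tests=1)
        single = {
            k: scan_snps(aer, ds.genotypes, "G", [k], ["s1"], m_tests=1)
            for k in ("m1", "m2")
        }
        n_both = both["n_informative"].iloc[0]
        assert n_both >= max(
            s["n_informative"].iloc[0] for s in single.values()
        )

    def test_scan_recovers_simulated_effect(self, single_gene_dataset):
        cfg, ds, aer, _ = single_gene_dataset
        scan = scan_snps(aer, ds.genotypes, "GENE1", ["marker1"], ["snp1"], m_tests=1)
        row = scan.iloc[0]
        assert not row["excluded"]
        assert row["beta"] == pytest.approx(math.log(1.5), abs=0.1)
        assert row["fold"] == pytest.approx(1.5, abs=0.15)
        assert row["p"] < 1e-10
        assert row["fwer"] == pytest.approx(min(1.0, row["p"]), rel=1e-9)
        assert top_snp(scan) == "snp1"

    def test_ungenotyped_snp_flagged_scan_continues(self, single_gene_dataset):
        cfg, ds, aer, _ = single_gene_dataset
        scan = scan_snps(
            aer, ds.genotypes, "GENE1", ["marker1"], ["snp1", "ghost"], m_tests=2
        )
        ghost = scan.set_index("snp_id").loc["ghost"]
        assert bool(ghost["excluded"]) and ghost["reason"] == "not genotyped"
        assert not bool(scan.set_index("snp_id").loc["snp1", "excluded"])


class TestStratifiedAER:
    def test_identical_groups_no_difference(self):
        vals = [0.9, 1.0, 1.1, 1.2]
        aer = pd.DataFrame(
            {
                "individual_id": list(range(8)),
                "marker_id": "m",
                "norm_ratio": vals * 2,
            }
        )
        calls = pd.DataFrame(
            {"cond": [0.0] * 4 + [1.0] * 4, "m": [1.0] * 8}, index=range(8)
        )
        snps = pd.DataFrame(
            {"chrom": "9", "pos": [1, 2], "allele_a": "A", "allele_b": "G"},
            index=["cond", "m"],
        )
        geno = GenotypeTable(calls=calls, snps=snps)
        res = stratified_aer(aer, geno, "m", "cond")
        assert res["mannwhitney_p"] == pytest.approx(1.0, abs=0.05)
        assert res["group_means"][0] == pytest.approx(res["group_means"][1])

    def test_double_heterozygotes_show_larger_imbalance(self):
        """With a causal SNP in strong coupling LD, marker heterozygotes who
        also carry the causal het show a larger mean ratio."""
        cfg = single_gene_config(
            n_individuals=400, beta=math.log(2.0), dprime=0.95, seed=21
        )
        ds = simulate(cfg)
        aer, gdna = normalize_dataset(ds, {"marker1": "GENE1"})
        res = stratified_aer(aer, ds.genotypes, "marker1", "snp1", gdna=gdna)
        means = res["group_means"]
        assert means[1] > means.get(0, 1.0)
        assert res["mannwhitney_p"] < 0.01
        assert res["gdna_mean_ratio"] == pytest.approx(1.0, abs=0.01)


class TestFold:
    @pytest.mark.parametrize("beta,fold", [(0.0, 1.0), (LN2, 2.0), (-LN2, 0.5)])
    def test_fold_convention(self, beta, fold):
        assert effect_to_fold(beta) == pytest.approx(fold)
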