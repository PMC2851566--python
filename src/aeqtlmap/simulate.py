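"""Synthetic two-cohort genotype/expression data with known cis architecture.

The generator emulates the study design the analysis assumes: two cohorts of
different ancestry (a larger admixed cohort with lower LD and a smaller
European-ancestry cohort with stronger LD), a panel of mapping SNPs plus two
transcribed SNPs per gene for three genes, lognormal allele-level expression
with additive cis effects at chosen SNPs, trans effects (age, sex, ethnicity
and a residual) acting on both alleles equally, assay-specific multiplicative
bias, and replicated ratio/Ct measurements.

The generative model mirrors the analysis model exactly: per haplotype ``a``

    log expr_a = baseline_gene + sum_i beta_i * allele_a(SNP i) + trans,

so the cDNA allelic ratio of a marker heterozygote is
``exp(cis_num - cis_other) * assay_bias * noise`` (trans cancels), the gDNA
ratio is ``assay_bias * noise``, and total expression is the sum of the two
allele levels.  A truth record (haplotypes, effects, analytic per-allele cis
variance and cis fraction) supports parameter-recovery tests.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    ETHNICITY_CATEGORIES,
    GenotypeTable,
    LN2,
    write_genotypes_tsv,
    write_genotypes_vcf,
)

__all__ = [
    "TransModel",
    "CohortSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "SimulationError",
    "simulate_haplotypes",
    "simulate_expression",
    "simulate",
    "simulate_mixing_series",
    "default_config",
    "single_gene_config",
    "write_dataset",
]

REFERENCE_GENES = {"ct_b2m": 18.0, "ct_gapd": 19.0, "ct_hprt1": 24.0}


class SimulationError(ValueError):
    pass


@dataclass
class TransModel:
    """Trans-acting (both-allele) influences on log expression."""

    age_coef: float = 0.008          # per year, natural-log scale
    sex_coef: float = 0.05           # M vs F
    ethnicity_effects: dict = field(
        default_factory=lambda: {
            "Cape mixed-ancestry": 0.0,
            "black African": -0.10,
            "white": 0.05,
            "Indian": 0.0,
            "other": 0.0,
        }
    )
    resid_sd: float = 0.65           # residual trans SD, natural-log scale
    age_range: tuple = (20.0, 60.0)


@dataclass
class CohortSpec:
    name: str
    n_individuals: int
    haplotype_freqs: list[float]
    ethnicity_probs: dict = field(
        default_factory=lambda: {"white": 0.97, "other": 0.03}
    )

    def validate(self, n_haps: int) -> None:
        if self.n_individuals < 1:
            raise SimulationError(f"cohort {self.name}: n_individuals must be >= 1")
        if len(self.haplotype_freqs) != n_haps:
            raise SimulationError(
                f"cohort {self.name}: {len(self.haplotype_freqs)} frequencies "
                f"for {n_haps} haplotypes"
            )
        f = np.asarray(self.haplotype_freqs, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise SimulationError(
                f"cohort {self.name}: haplotype frequencies must be nonnegative "
                "and sum to 1 within 1e-9"
            )
        for eth in self.ethnicity_probs:
            if eth not in ETHNICITY_CATEGORIES:
                raise SimulationError(f"unknown ethnicity category {eth!r}")
        if abs(sum(self.ethnicity_probs.values()) - 1.0) > 1e-9:
            raise SimulationError(f"cohort {self.name}: ethnicity probs must sum to 1")


@dataclass
class SimulationConfig:
    """Full generative specification; ``seed`` fixes every random draw."""

    snp_ids: list[str]
    haplotypes: list[str]            # '0'/'1' strings over snp_ids
    cohorts: list[CohortSpec]
    genes: dict                      # gene -> [transcribed marker ids]
    cis_effects: dict                # gene -> {snp_id: beta (ln fold / copy)}
    marker_sd: dict                  # marker -> sigma_k (log scale)
    assay_bias: dict                 # marker -> multiplicative bias
    trans: TransModel = field(default_factory=TransModel)
    baseline_log_expr: dict = field(default_factory=dict)   # gene -> baseline
    ct_baseline: dict = field(default_factory=dict)         # gene -> Ct at T=1
    ct_sd: float = 0.15
    loading_sd: float = 0.30         # per-individual RNA loading (cancels in dCt)
    replicate_cv: float = 0.05
    n_replicates: int = 4
    missing_rate: float = 0.0
    positions: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise SimulationError("empty haplotype pool")
        s = len(self.snp_ids)
        for h in self.haplotypes:
            if len(h) != s or set(h) - {"0", "1"}:
                raise SimulationError(f"bad haplotype string {h!r}")
        for cohort in self.cohorts:
            cohort.validate(len(self.haplotypes))
        hap_mat = self.hap_matrix()
        for gene, markers in self.genes.items():
            for k in markers:
                if k not in self.snp_ids:
                    raise SimulationError(f"marker {k!r} not among SNPs")
                col = hap_mat[:, self.snp_ids.index(k)]
                if col.min() == col.max():
                    raise SimulationError(
                        f"marker {k!r} is monomorphic in the haplotype pool: "
                        "no heterozygote can ever be observed there"
                    )
        for gene, eff in self.cis_effects.items():
            if gene not in self.genes:
                raise SimulationError(f"cis effects for unknown gene {gene!r}")
            for snp in eff:
                if snp not in self.snp_ids:
                    raise SimulationError(f"cis-effect SNP {snp!r} not on haplotypes")
        for k, sd in self.marker_sd.items():
            if sd < 0:
                raise SimulationError(f"marker_sd[{k!r}] must be >= 0")
        if self.replicate_cv < 0:
            raise SimulationError("replicate_cv must be >= 0")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.positions is None:
            self.positions = list(range(1, s + 1))
        for gene in self.genes:
            self.baseline_log_expr.setdefault(gene, 0.0)
            self.ct_baseline.setdefault(gene, 26.0)

    def hap_matrix(self) -> np.ndarray:
        return np.array([[int(c) for c in h] for h in self.haplotypes], dtype=np.int8)

    @property
    def marker_ids(self) -> list[str]:
        return [k for ms in self.genes.values() for k in ms]

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["trans"] = asdict(self.trans)
        d["cohorts"] = [asdict(c) for c in self.cohorts]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if isinstance(d.get("trans"), dict):
            d["trans"] = TransModel(**d["trans"])
        d["cohorts"] = [
            CohortSpec(**c) if isinstance(c, dict) else c for c in d["cohorts"]
        ]
        if "positions" in d and d["positions"] is not None:
            d["positions"] = list(d["positions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedDataset:
    genotypes: GenotypeTable
    aer_measurements: pd.DataFrame   # individual_id, marker_id, template, replicate, ratio
    ct: pd.DataFrame                 # individual_id, gene, replicate, ct_target, ct_*
    covariates: pd.DataFrame         # individual_id, age, sex, ethnicity, cohort
    truth: dict


# ---------------------------------------------------------------------------
# haplotype sampling


def simulate_haplotypes(cfg: SimulationConfig, cohort: str) -> np.ndarray:
    """Draw paired haplotypes (indices into the pool) for one cohort.

    Each individual receives two independent draws from the cohort's
    haplotype distribution: random mating, i.e. HWE at the haplotype level.
    """
    spec = _cohort(cfg, cohort)
    rng = np.random.default_rng([cfg.seed, _cohort_index(cfg, cohort), 1])
    f = np.asarray(spec.haplotype_freqs, dtype=float)
    return rng.choice(len(f), size=(spec.n_individuals, 2), p=f / f.sum())


def _cohort(cfg: SimulationConfig, name: str) -> CohortSpec:
    for c in cfg.cohorts:
        if c.name == name:
            return c
    raise SimulationError(f"no cohort named {name!r}")


def _cohort_index(cfg: SimulationConfig, name: str) -> int:
    return [c.name for c in cfg.cohorts].index(name)


def _simulate_covariates(cfg: SimulationConfig, cohort: str) -> pd.DataFrame:
    spec = _cohort(cfg, cohort)
    rng = np.random.default_rng([cfg.seed, _cohort_index(cfg, cohort), 2])
    n = spec.n_individuals
    lo, hi = cfg.trans.age_range
    eths = list(spec.ethnicity_probs)
    probs = np.array([spec.ethnicity_probs[e] for e in eths])
    return pd.DataFrame(
        {
            "individual_id": [f"{cohort}_{i:04d}" for i in range(n)],
            "age": np.round(rng.uniform(lo, hi, size=n), 1),
            "sex": rng.choice(["F", "M"], size=n),
            "ethnicity": rng.choice(eths, size=n, p=probs / probs.sum()),
            "cohort": cohort,
        }
    )


# ---------------------------------------------------------------------------
# expression & measurement


def simulate_expression(
    haplotypes: np.ndarray,
    cfg: SimulationConfig,
    cohort: str,
    covariates: pd.DataFrame | None = None,
) -> SimulatedDataset:
    """Generate genotype, AER, Ct and covariate tables for one cohort.

    ``haplotypes`` is the (n, 2) index array from :func:`simulate_haplotypes`.
    """
    spec = _cohort(cfg, cohort)
    ci = _cohort_index(cfg, cohort)
    rng = np.random.default_rng([cfg.seed, ci, 3])
    if covariates is None:
        covariates = _simulate_covariates(cfg, cohort)
    ids = covariates["individual_id"].tolist()
    n = len(ids)
    if haplotypes.shape != (n, 2):
        raise SimulationError("haplotype array does not match cohort size")

    hap_mat = cfg.hap_matrix()
    snp_pos = {s: i for i, s in enumerate(cfg.snp_ids)}
    h1 = hap_mat[haplotypes[:, 0]]
    h2 = hap_mat[haplotypes[:, 1]]
    calls = (h1 + h2).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = np.nan
    calls_df = pd.DataFrame(calls, index=pd.Index(ids, name="individual_id"),
                            columns=cfg.snp_ids)
    snps_meta = pd.DataFrame(
        {"chrom": "9", "pos": cfg.positions, "allele_a": "A", "allele_b": "G"},
        index=cfg.snp_ids,
    )
    geno = GenotypeTable(
        calls=calls_df, snps=snps_meta,
        cohorts=pd.Series(cohort, index=calls_df.index),
    )

    # trans contribution shared by both alleles, per gene
    tm = cfg.trans
    eth_eff = covariates["ethnicity"].map(tm.ethnicity_effects).fillna(0.0).to_numpy()
    base_trans = (
        tm.age_coef * covariates["age"].to_numpy()
        + tm.sex_coef * (covariates["sex"] == "M").to_numpy(dtype=float)
        + eth_eff
    )
    rep_sd = math.sqrt(math.log(1.0 + cfg.replicate_cv**2))
    loading = rng.normal(0.0, cfg.loading_sd, size=n)

    aer_rows, ct_rows = [], []
    log_total = {}
    for gene, markers in cfg.genes.items():
        eff = cfg.cis_effects.get(gene, {})
        beta = np.zeros(len(cfg.snp_ids))
        for snp, b in eff.items():
            beta[snp_pos[snp]] = b
        c1 = h1 @ beta
        c2 = h2 @ beta
        trans = base_trans + rng.normal(0.0, tm.resid_sd, size=n)
        x1 = cfg.baseline_log_expr[gene] + c1 + trans
        x2 = cfg.baseline_log_expr[gene] + c2 + trans
        total = np.exp(x1) + np.exp(x2)
        log_total[gene] = np.log(total)

        for k in markers:
            kp = snp_pos[k]
            bias = cfg.assay_bias.get(k, 1.0)
            sd_k = cfg.marker_sd.get(k, 0.0)
            het = h1[:, kp] != h2[:, kp]
            # orientation: numerator allele is the coded allele '1'
            num_is_h1 = h1[:, kp] == 1
            true_log_ratio = np.where(num_is_h1, c1 - c2, c2 - c1)
            assay_err = rng.normal(0.0, sd_k, size=n) if sd_k > 0 else np.zeros(n)
            for j in np.flatnonzero(het):
                for r in range(cfg.n_replicates):
                    noise = rng.normal(0.0, rep_sd) if rep_sd > 0 else 0.0
                    aer_rows.append(
                        {
                            "individual_id": ids[j],
                            "marker_id": k,
                            "template": "cDNA",
                            "replicate": r + 1,
                            "ratio": float(
                                math.exp(true_log_ratio[j] + assay_err[j] + noise)
                                * bias
                            ),
                        }
                    )
                    gnoise = rng.normal(0.0, rep_sd) if rep_sd > 0 else 0.0
                    aer_rows.append(
                        {
                            "individual_id": ids[j],
                            "marker_id": k,
                            "template": "gDNA",
                            "replicate": r + 1,
                            "ratio": float(bias * math.exp(gnoise)),
                        }
                    )

        ct0 = cfg.ct_baseline[gene]
        for j in range(n):
            for r in range(cfg.n_replicates):
                row = {
                    "individual_id": ids[j],
                    "gene": gene,
                    "replicate": r + 1,
                    "ct_target": float(
                        ct0 - log_total[gene][j] / LN2 + loading[j]
                        + (rng.normal(0.0, cfg.ct_sd) if cfg.ct_sd > 0 else 0.0)
                    ),
                }
                for ref, mean in REFERENCE_GENES.items():
                    row[ref] = float(
                        mean + loading[j]
                        + (rng.normal(0.0, cfg.ct_sd) if cfg.ct_sd > 0 else 0.0)
                    )
                ct_rows.append(row)

    truth = {
        "cohort": cohort,
        "haplotypes": {
            ids[j]: [cfg.haplotypes[haplotypes[j, 0]], cfg.haplotypes[haplotypes[j, 1]]]
            for j in range(n)
        },
        "beta": {g: dict(e) for g, e in cfg.cis_effects.items()},
        **_analytic_truth(cfg, [cohort]),
    }
    return SimulatedDataset(
        genotypes=geno,
        aer_measurements=pd.DataFrame(aer_rows),
        ct=pd.DataFrame(ct_rows),
        covariates=covariates,
        truth=truth,
    )


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate all cohorts and concatenate into one dataset."""
    parts = []
    for spec in cfg.cohorts:
        haps = simulate_haplotypes(cfg, spec.name)
        parts.append(simulate_expression(haps, cfg, spec.name))
    calls = pd.concat([p.genotypes.calls for p in parts])
    cohorts = pd.concat([p.genotypes.cohorts for p in parts])
    geno = GenotypeTable(calls=calls, snps=parts[0].genotypes.snps, cohorts=cohorts)
    truth = {
        "beta": parts[0].truth["beta"],
        "haplotypes": {k: v for p in parts for k, v in p.truth["haplotypes"].items()},
        **_analytic_truth(cfg, [c.name for c in cfg.cohorts]),
        "per_cohort": {p.truth["cohort"]: {kk: p.truth[kk] for kk in
                       ("cis_variance", "total_variance", "cis_fraction")}
                      for p in parts},
    }
    return SimulatedDataset(
        genotypes=geno,
        aer_measurements=pd.concat(
            [p.aer_measurements for p in parts], ignore_index=True
        ),
        ct=pd.concat([p.ct for p in parts], ignore_index=True),
        covariates=pd.concat([p.covariates for p in parts], ignore_index=True),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# analytic truth record


def _analytic_truth(cfg: SimulationConfig, cohort_names: list[str]) -> dict:
    """Exact per-allele cis variance and cis fraction of log total expression.

    The haplotype pool is a finite distribution, so the variance of the
    per-allele cis contribution and of log(e^{c1} + e^{c2}) are computed by
    enumeration; covariate and measurement variances are closed-form.  Across
    cohorts the quantities combine by the law of total variance with weights
    proportional to cohort size.
    """
    hap_mat = cfg.hap_matrix()
    snp_pos = {s: i for i, s in enumerate(cfg.snp_ids)}
    tm = cfg.trans
    lo, hi = tm.age_range
    var_age = tm.age_coef**2 * (hi - lo) ** 2 / 12.0
    mean_age = tm.age_coef * (lo + hi) / 2.0
    var_sex = tm.sex_coef**2 * 0.25
    mean_sex = tm.sex_coef * 0.5
    var_meas = LN2**2 * (4.0 / 3.0) * cfg.ct_sd**2 / cfg.n_replicates

    specs = [_cohort(cfg, name) for name in cohort_names]
    weights = np.array([s.n_individuals for s in specs], dtype=float)
    weights /= weights.sum()

    cis_var, total_var, frac = {}, {}, {}
    for gene in cfg.genes:
        beta = np.zeros(len(cfg.snp_ids))
        for snp, b in cfg.cis_effects.get(gene, {}).items():
            beta[snp_pos[snp]] = b
        c = hap_mat @ beta  # cis contribution per pool haplotype

        e1 = e2 = 0.0          # allele-level moments of c
        ey = ey2 = 0.0         # moments of S = trans-mean + log(e^c1 + e^c2)
        for w, spec in zip(weights, specs):
            f = np.asarray(spec.haplotype_freqs, dtype=float)
            ec = float(f @ c)
            ec2 = float(f @ c**2)
            e1 += w * ec
            e2 += w * ec2
            # pair term, exact over the pool x pool grid
            pair = np.log(np.exp(c)[:, None] + np.exp(c)[None, :])
            pw = f[:, None] * f[None, :]
            ep = float((pw * pair).sum())
            ep2 = float((pw * pair**2).sum())
            eth_mean = sum(
                p * tm.ethnicity_effects.get(e, 0.0)
                for e, p in spec.ethnicity_probs.items()
            )
            eth_var = sum(
                p * tm.ethnicity_effects.get(e, 0.0) ** 2
                for e, p in spec.ethnicity_probs.items()
            ) - eth_mean**2
            mean_s = mean_age + mean_sex + eth_mean + ep
            var_s = var_age + var_sex + eth_var + tm.resid_sd**2 + (ep2 - ep**2)
            ey += w * mean_s
            ey2 += w * (var_s + mean_s**2)
        v_cis = e2 - e1**2
        v_tot = (ey2 - ey**2) + var_meas
        cis_var[gene] = v_cis
        total_var[gene] = v_tot
        frac[gene] = v_cis / v_tot if v_tot > 0 else float("nan")
    return {"cis_variance": cis_var, "total_variance": total_var, "cis_fraction": frac}


# ---------------------------------------------------------------------------
# mixing series


def simulate_mixing_series(
    marker_id: str,
    levels=(8.0, 4.0, 1.0, 0.25, 0.125),
    bias: float = 1.0,
    replicate_cv: float = 0.05,
    n_replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Assay response to templates mixed at known allele-1:allele-2 ratios.

    Mirrors the wet-lab linearity check in which PCR products from opposite
    homozygotes are mixed 8:1, 4:1, 1:1, 1:4, 1:8 and measured with the
    allelic-ratio assay; the measured ratio is level x bias x replicate noise.
    """
    levels = [float(x) for x in levels]
    if any(x <= 0 for x in levels):
        raise SimulationError("mixing levels must be positive")
    rng = np.random.default_rng([seed, 17])
    rep_sd = math.sqrt(math.log(1.0 + replicate_cv**2)) if replicate_cv > 0 else 0.0
    rows = []
    for level in levels:
        for r in range(n_replicates):
            noise = rng.normal(0.0, rep_sd) if rep_sd > 0 else 0.0
            rows.append(
                {
                    "marker_id": marker_id,
                    "level": level,
                    "replicate": r + 1,
                    "measured_ratio": level * bias * math.exp(noise),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default study-like configuration


def _block_founders(rng: np.random.Generator, n_loci: int, n_founders: int) -> np.ndarray:
    """Founder haplotypes for one LD block, every locus polymorphic."""
    p = rng.uniform(0.25, 0.75, size=n_loci)
    founders = (rng.random((n_founders, n_loci)) < p).astype(np.int8)
    for locus in range(n_loci):
        col = founders[:, locus]
        if col.min() == col.max():
            founders[rng.integers(n_founders), locus] = 1 - col[0]
    return founders


def _recombine(rng: np.random.Generator, founders: np.ndarray, n_rec: int) -> np.ndarray:
    out = []
    for _ in range(n_rec):
        a, b = rng.choice(len(founders), size=2, replace=False)
        cut = rng.integers(1, founders.shape[1])
        out.append(np.concatenate([founders[a, :cut], founders[b, cut:]]))
    return np.array(out, dtype=np.int8)


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-like defaults: 56-SNP panel, 3 genes x 2 transcribed markers,
    a 310-individual admixed cohort (lower LD, its own frequencies) and a
    177-individual European-ancestry cohort (stronger LD).

    The pool is three independent LD blocks (one per gene region); within a
    block the European-ancestry pool holds four founder haplotypes and the
    admixed pool adds recombinants, lowering LD.  Cis effects are chosen to
    echo the locus's architecture: the ANRIL transcribed SNP rs564398 drives
    ANRIL up (~1.6-fold) and CDKN2B down (antisense pattern), with further
    independent effects inside each gene's own block.
    """
    pool_rng = np.random.default_rng(20090921)  # pool structure is fixed design
    blocks = {
        "A": {"loci": ["rs7036656"] + [f"snpA{i:02d}" for i in range(1, 16)]
               + ["rs3088440", "rs11515"], "founders": 4, "rec": 5},
        "B": {"loci": ["rs3218018", "rs3814960"] + [f"snpB{i:02d}" for i in range(1, 15)]
               + ["rs3217992", "rs1063192"], "founders": 4, "rec": 5},
        "N": {"loci": [f"snpN{i:02d}" for i in range(1, 18)]
               + ["rs10965215", "rs564398", "rs7865618"], "founders": 4, "rec": 5},
    }
    block_haps_cau, block_haps_sa, block_freq_cau, block_freq_sa = {}, {}, {}, {}
    for name, spec in blocks.items():
        founders = _block_founders(pool_rng, len(spec["loci"]), spec["founders"])
        rec = _recombine(pool_rng, founders, spec["rec"])
        block_haps_cau[name] = founders
        block_haps_sa[name] = np.concatenate([founders, rec])
        f_cau = pool_rng.dirichlet(np.full(len(founders), 2.0))
        f_sa = pool_rng.dirichlet(np.full(len(founders) + len(rec), 2.0))
        block_freq_cau[name] = f_cau
        block_freq_sa[name] = f_sa

    snp_ids = [s for spec in blocks.values() for s in spec["loci"]]

    def assemble(block_haps, block_freqs):
        haps, freqs = [], []
        names = list(blocks)
        for combo in itertools.product(*[range(len(block_haps[b])) for b in names]):
            hap = np.concatenate([block_haps[b][i] for b, i in zip(names, combo)])
            haps.append("".join(map(str, hap)))
            freqs.append(float(np.prod([block_freqs[b][i] for b, i in zip(names, combo)])))
        return haps, freqs

    haps_sa, freqs_sa = assemble(block_haps_sa, block_freq_sa)
    haps_cau_raw, freqs_cau = assemble(block_haps_cau, block_freq_cau)
    # one shared haplotype list: the Caucasian pool assigns zero frequency to
    # haplotypes carrying SA-only recombinant blocks
    freq_cau_map = dict(zip(haps_cau_raw, freqs_cau))
    freqs_cau_full = [freq_cau_map.get(h, 0.0) for h in haps_sa]
    total = sum(freqs_cau_full)
    freqs_cau_full = [f / total for f in freqs_cau_full]

    genes = {
        "CDKN2A": ["rs3088440", "rs11515"],
        "CDKN2B": ["rs3217992", "rs1063192"],
        "ANRIL": ["rs10965215", "rs564398"],
    }
    cis_effects = {
        "CDKN2A": {"rs7036656": math.log(1.4)},
        "CDKN2B": {"rs3218018": math.log(1.33), "rs564398": -math.log(1.2)},
        "ANRIL": {"rs564398": math.log(1.6), "rs7865618": math.log(1.2)},
    }
    marker_sd = {
        "rs3088440": 0.15, "rs11515": 0.15,
        "rs3217992": 0.12, "rs1063192": 0.12,
        "rs10965215": 0.25, "rs564398": 0.25,
    }
    assay_bias = {
        "rs3088440": 1.20, "rs11515": 0.90,
        "rs3217992": 1.10, "rs1063192": 1.05,
        "rs10965215": 0.80, "rs564398": 1.30,
    }
    cohorts = [
        CohortSpec(
            name="SA", n_individuals=310, haplotype_freqs=freqs_sa,
            ethnicity_probs={
                "Cape mixed-ancestry": 0.70, "black African": 0.20,
                "white": 0.05, "Indian": 0.04, "other": 0.01,
            },
        ),
        CohortSpec(
            name="CAU", n_individuals=177, haplotype_freqs=freqs_cau_full,
            ethnicity_probs={"white": 0.97, "other": 0.03},
        ),
    ]
    return SimulationConfig(
        snp_ids=snp_ids,
        haplotypes=haps_sa,
        cohorts=cohorts,
        genes=genes,
        cis_effects=cis_effects,
        marker_sd=marker_sd,
        assay_bias=assay_bias,
        ct_baseline={"CDKN2A": 25.0, "CDKN2B": 24.0, "ANRIL": 28.0},
        seed=seed,
    )


def single_gene_config(
    n_individuals: int = 300,
    beta: float = math.log(1.5),
    marker_sd: float = 0.2,
    p_snp: float = 0.5,
    p_marker: float = 0.5,
    dprime: float = 0.8,
    assay_bias: float = 1.2,
    trans_sd: float = 0.65,
    replicate_cv: float = 0.05,
    n_replicates: int = 4,
    ct_sd: float = 0.15,
    seed: int = 0,
    cohort_name: str = "SIM",
    gene: str = "GENE1",
) -> SimulationConfig:
    """Minimal one-gene scenario: one mapping SNP, one transcribed marker.

    The two-locus haplotype frequencies are set from the allele frequencies
    and a target D' (positive coupling), giving direct control over the
    phase information available to the mixture likelihood.  Used for
    calibration and recovery experiments.
    """
    if not (0 < p_snp < 1 and 0 < p_marker < 1):
        raise SimulationError("allele frequencies must be in (0, 1)")
    dmax = min(p_snp * (1 - p_marker), (1 - p_snp) * p_marker)
    d = dprime * dmax
    f11 = p_snp * p_marker + d
    f10 = p_snp * (1 - p_marker) - d
    f01 = (1 - p_snp) * p_marker - d
    f00 = (1 - p_snp) * (1 - p_marker) + d
    freqs = [f00, f01, f10, f11]
    if any(f < -1e-12 for f in freqs):
        raise SimulationError("requested D' is infeasible for these frequencies")
    freqs = [max(f, 0.0) for f in freqs]
    tm = TransModel(resid_sd=trans_sd)
    return SimulationConfig(
        snp_ids=["snp1", "marker1"],
        haplotypes=["00", "01", "10", "11"],
        cohorts=[
            CohortSpec(
                name=cohort_name, n_individuals=n_individuals,
                haplotype_freqs=freqs,
                ethnicity_probs={"white": 1.0},
            )
        ],
        genes={gene: ["marker1"]},
        cis_effects={gene: {"snp1": beta}} if beta != 0 else {gene: {}},
        marker_sd={"marker1": marker_sd},
        assay_bias={"marker1": assay_bias},
        trans=tm,
        ct_sd=ct_sd,
        replicate_cv=replicate_cv,
        n_replicates=n_replicates,
        seed=seed,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all tables of a simulated dataset as TSV/VCF/JSON text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_tsv": outdir / "genotypes.tsv",
        "genotypes_vcf": outdir / "genotypes.vcf",
        "aer": outdir / "aer.tsv",
        "ct": outdir / "ct.tsv",
        "covariates": outdir / "covariates.tsv",
        "truth": outdir / "truth.json",
    }
    write_genotypes_tsv(ds.genotypes, paths["genotypes_tsv"])
    write_genotypes_vcf(ds.genotypes, paths["genotypes_vcf"])
    ds.aer_measurements.to_csv(paths["aer"], sep="\t", index=False, float_format="%.6g")
    ds.ct.to_csv(paths["ct"], sep="\t", index=False, float_format="%.4f")
    ds.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    return paths
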