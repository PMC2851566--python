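"""End-to-end orchestration: simulate/load -> QC -> normalize -> scan -> summarize.

A single :class:`PipelineConfig` drives every stage; stages only consume
artifacts produced by earlier stages or paths declared in the config, and a
provenance record (config hash, seed, package version, output hashes) makes
reruns checkable for bit-identity.
"""
from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .eqtl import eqtl_regression
from .io import (
    GenotypeTable,
    aggregate_replicates,
    compute_normalization,
    delta_ct,
    normalize_aer,
    qc_filter,
    read_aer_measurements,
    read_genotypes,
)
from .model import scan_snps, top_snp
from .phasing import em_haplotype_freqs, ld_stats
from .simulate import SimulationConfig, default_config, simulate, write_dataset
from .summary import (
    cis_variance_fraction,
    compare_scans,
    direction_concordance,
    fwer_thresholds,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full mapping run."""

    out_dir: str = "aeqtlmap_out"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "tsv"
    aer_path: str | None = None
    ct_path: str | None = None
    covariates_path: str | None = None
    genes: dict = field(default_factory=dict)        # gene -> [marker ids]
    snp_list: list[str] | None = None
    min_informative: int = 8
    alpha: float = 0.05
    m_tests: int | None = None
    normalization_strategy: str = "population-mean"
    outlier_z: float = 3.0
    min_call_rate: float = 0.8
    hwe_alpha: float = 0.001
    adjust_rounds: int = 1
    n_starts: int = 5

    def validate(self) -> None:
        if self.simulate:
            if self.simulation is None:
                self.simulation = default_config(seed=self.seed)
            if not self.genes:
                self.genes = dict(self.simulation.genes)
        else:
            for name in ("genotypes_path", "aer_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} is required when simulate is false")
            if not self.genes:
                raise ValueError("genes (gene -> markers) must be configured")
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("simulation", None)
        cfg = cls(**d)
        if sim:
            cfg.simulation = SimulationConfig.from_dict(sim)
        return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write artifacts plus provenance.

    Returns a result bundle with the QC report, scan tables (unadjusted and
    sequentially adjusted), eQTL results, LD, variance decomposition, and
    cross-comparisons.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if cfg.simulate:
            ds = simulate(cfg.simulation)
            write_dataset(ds, out / "simulated")
            genotypes = ds.genotypes
            aer_raw = ds.aer_measurements
            ct = ds.ct
            covariates = ds.covariates
        else:
            genotypes = read_genotypes(cfg.genotypes_path, fmt=cfg.genotypes_format)
            aer_raw = read_aer_measurements(cfg.aer_path)
            ct = pd.read_csv(cfg.ct_path, sep="\t") if cfg.ct_path else None
            covariates = (
                pd.read_csv(cfg.covariates_path, sep="\t")
                if cfg.covariates_path else None
            )

        stage = "qc"
        genotypes, qc_report = qc_filter(
            genotypes, min_call_rate=cfg.min_call_rate, hwe_alpha=cfg.hwe_alpha
        )
        qc_report["hwe"].to_csv(out / "qc_hwe.tsv", sep="\t", index=False)

        stage = "normalize"
        agg = aggregate_replicates(aer_raw)
        factors = compute_normalization(
            agg[agg["template"] == "gDNA"], strategy=cfg.normalization_strategy
        )
        marker_genes = {k: g for g, ms in cfg.genes.items() for k in ms}
        aer = normalize_aer(agg[agg["template"] == "cDNA"], factors, marker_genes)
        gdna_norm = normalize_aer(
            agg[agg["template"] == "gDNA"].assign(template="cDNA"),
            factors, marker_genes,
        )
        aer.to_csv(out / "aer_normalized.tsv", sep="\t", index=False)

        stage = "expression"
        expression = delta_ct(ct) if ct is not None else None
        if expression is not None:
            expression.to_csv(out / "total_expression.tsv", sep="\t", index=False)

        stage = "ld"
        all_markers = [k for ms in cfg.genes.values() for k in ms]
        snp_list = cfg.snp_list or genotypes.snp_ids
        m = cfg.m_tests if cfg.m_tests is not None else len(snp_list)
        ld_tables = {}
        for cohort, calls in _cohorts(genotypes):
            model = em_haplotype_freqs(
                calls.dropna(subset=all_markers), all_markers, cohort=cohort
            )
            ld_tables[cohort] = ld_stats(model)
            ld_tables[cohort].to_csv(out / f"ld_{cohort}.tsv", sep="\t", index=False)

        stage = "scan"
        scans: dict[str, list[pd.DataFrame]] = {}
        for gene, markers in cfg.genes.items():
            rounds = []
            adjust: list[str] = []
            for rnd in range(cfg.adjust_rounds + 1):
                scan = scan_snps(
                    aer, genotypes, gene, markers, snp_list,
                    adjust=adjust, min_informative=cfg.min_informative,
                    m_tests=m, n_starts=cfg.n_starts, seed=cfg.seed,
                )
                scan.to_csv(
                    out / f"scan_{gene}_round{rnd}.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
                rounds.append(scan)
                best = top_snp(scan)
                if best is None or rnd == cfg.adjust_rounds:
                    break
                adjust = adjust + [best]
            scans[gene] = rounds

        stage = "eqtl"
        eqtl = None
        if expression is not None:
            eqtl = eqtl_regression(
                expression, genotypes, covariates, snp_ids=snp_list,
                outlier_z=cfg.outlier_z, m_tests=m,
            )
            eqtl.to_csv(out / "eqtl.tsv", sep="\t", index=False, float_format="%.6g")

        stage = "summarize"
        thresholds = fwer_thresholds(alpha=cfg.alpha, m_tests=m)
        decomposition = []
        if expression is not None:
            for gene, markers in cfg.genes.items():
                vals = aer.loc[aer["marker_id"].isin(markers), "log_ratio"]
                tot = expression.loc[expression["gene"] == gene, "log_expr"]
                if len(vals) >= 2 and len(tot) >= 2:
                    decomposition.append(
                        cis_variance_fraction(
                            vals.to_numpy(), tot.to_numpy(), gene=gene,
                            marker_id="+".join(markers),
                        )
                    )
        comparisons = {}
        if eqtl is not None:
            for gene in cfg.genes:
                try:
                    comparisons[f"aeqtl_vs_eqtl_{gene}"] = {
                        k: v for k, v in compare_scans(
                            scans[gene][0], eqtl[eqtl["gene"] == gene]
                        ).items() if k != "table"
                    }
                except ValueError as err:
                    logger.warning("comparison skipped for %s: %s", gene, err)
        concordance = direction_concordance(
            {g: s[0] for g, s in scans.items()}, fwer_threshold=cfg.alpha
        ) if len(cfg.genes) >= 2 else None
        if concordance is not None:
            concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)
        summary = {
            "thresholds": thresholds,
            "cis_variance": decomposition,
            "comparisons": comparisons,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=str)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    provenance = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_fingerprint(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            p.name: _hash_file(p) for p in sorted(out.rglob("*")) if p.is_file()
            and p.name != "provenance.json"
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)

    return {
        "genotypes": genotypes,
        "qc": qc_report,
        "aer": aer,
        "gdna": gdna_norm,
        "expression": expression,
        "ld": ld_tables,
        "scans": scans,
        "eqtl": eqtl,
        "summary": summary,
        "concordance": concordance,
        "provenance": provenance,
    }


def _cohorts(genotypes: GenotypeTable):
    if genotypes.cohorts is None:
        yield "all", genotypes.calls
        return
    for c in pd.unique(genotypes.cohorts):
        ids = genotypes.cohorts.index[genotypes.cohorts == c]
        yield str(c), genotypes.calls.loc[genotypes.calls.index.intersection(ids)]


def _config_fingerprint(cfg: PipelineConfig) -> dict:
    d = {k: v for k, v in vars(cfg).items() if k != "simulation"}
    if cfg.simulation is not None:
        d["simulation"] = {
            "snp_ids": cfg.simulation.snp_ids,
            "seed": cfg.simulation.seed,
            "cohorts": [
                (c.name, c.n_individuals) for c in cfg.simulation.cohorts
            ],
        }
    return d
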