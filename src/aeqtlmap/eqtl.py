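"""Total-expression (eQTL) arm: OLS of log expression on additive genotype.

Complements the allelic analysis: total expression reflects both cis and
trans influences, so genotype slopes are fitted with age, sex and ethnicity
as covariates and an algorithmic outlier rule standing in for by-eye
exclusion.  Effects are reported as fold change per two allele copies so
they are directly comparable with the allelic-effect scale.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ETHNICITY_CATEGORIES, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["detect_outliers", "eqtl_regression"]


def detect_outliers(
    expression: pd.DataFrame, z_threshold: float = 3.0
) -> tuple[list, pd.DataFrame]:
    """Per-gene z-score rule standing in for visual outlier exclusion.

    Individuals with \\|z\\| > ``z_threshold`` on a gene's log expression are
    excluded from that gene's regressions.  Returns the excluded
    (individual, gene) report and logs each exclusion.
    """
    rows = []
    for gene, grp in expression.groupby("gene"):
        vals = grp["log_expr"]
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (vals - vals.mean()) / sd
        for idx in grp.index[np.abs(z) > z_threshold]:
            rows.append(
                {
                    "individual_id": grp.loc[idx, "individual_id"],
                    "gene": gene,
                    "z": float(z.loc[idx]),
                }
            )
            logger.info(
                "outlier: %s on %s (z=%.2f)", grp.loc[idx, "individual_id"],
                gene, z.loc[idx],
            )
    report = pd.DataFrame(rows, columns=["individual_id", "gene", "z"])
    return list(report["individual_id"]), report


def _covariate_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate design with closed-set ethnicity dummies.

    Categories with a single member make the design singular; they are merged
    into "other" with a warning before dummy coding.
    """
    cov = cov.copy()
    eth = cov["ethnicity"].where(
        cov["ethnicity"].isin(ETHNICITY_CATEGORIES), "other"
    )
    counts = eth.value_counts()
    for cat in counts.index[counts < 2]:
        if cat != "other":
            logger.warning("merging singleton ethnicity category %r into 'other'", cat)
            eth = eth.replace(cat, "other")
    cols = {"age": cov["age"].astype(float),
            "sex_M": (cov["sex"] == "M").astype(float)}
    present = [c for c in eth.unique()]
    ref = present[0]  # first observed category is the reference level
    for cat in present[1:]:
        cols[f"eth_{cat}"] = (eth == cat).astype(float)
    return pd.DataFrame(cols, index=cov.index)


def eqtl_regression(
    expression: pd.DataFrame,
    genotypes: GenotypeTable,
    covariates: pd.DataFrame | None = None,
    snp_ids: list[str] | None = None,
    gene: str | None = None,
    outlier_z: float | None = 3.0,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Per-SNP linear regression of log total expression on genotype.

    ``expression`` comes from :func:`aeqtlmap.io.delta_ct` (columns
    ``individual_id, gene, log_expr``).  Genotype is coded additively
    (0/1/2 coded-allele copies, no dominance or interactions); covariates are
    optional.  Outliers are removed per gene before fitting when
    ``outlier_z`` is set.  Bonferroni FWER uses ``m_tests`` (default: number
    of SNPs tested), matching the allelic scan for comparability.
    """
    if gene is not None:
        expression = expression[expression["gene"] == gene]
    snp_ids = snp_ids or genotypes.snp_ids
    m = m_tests if m_tests is not None else len(snp_ids)
    rows = []
    for g, expr_g in expression.groupby("gene"):
        expr_g = expr_g.set_index("individual_id")
        n_out = 0
        if outlier_z is not None:
            out_ids, rep = detect_outliers(
                expr_g.reset_index(), z_threshold=outlier_z
            )
            n_out = len(out_ids)
            expr_g = expr_g.drop(index=out_ids, errors="ignore")
        for snp in snp_ids:
            if snp not in genotypes.calls.columns:
                continue
            df = expr_g.join(genotypes.calls[snp].rename("geno"), how="inner")
            df = df.dropna(subset=["geno", "log_expr"])
            if covariates is not None:
                cov = covariates.set_index("individual_id").loc[
                    covariates.set_index("individual_id").index.intersection(df.index)
                ]
                df = df.join(_covariate_design(cov), how="inner").dropna()
            classes = df["geno"].nunique()
            if classes < 2 or len(df) < 4:
                rows.append(_empty_row(snp, g, len(df), n_out, "monomorphic"))
                continue
            xcols = ["geno"] + [
                c for c in df.columns
                if c.startswith(("age", "sex_", "eth_"))
            ]
            X = sm.add_constant(df[xcols].astype(float), has_constant="add")
            try:
                fit = sm.OLS(df["log_expr"].astype(float), X).fit()
            except np.linalg.LinAlgError:  # pragma: no cover
                rows.append(_empty_row(snp, g, len(df), n_out, "singular design"))
                continue
            slope = float(fit.params["geno"])
            p = float(fit.pvalues["geno"])
            fwer = min(1.0, m * p)
            rows.append(
                {
                    "snp_id": snp, "gene": g,
                    "slope": slope,
                    "se": float(fit.bse["geno"]),
                    "t": float(fit.tvalues["geno"]),
                    "p": p,
                    "neg_log10_p": -math.log10(p) if p > 0 else np.inf,
                    "fwer": fwer,
                    "neg_log10_fwer": -math.log10(fwer) if fwer > 0 else np.inf,
                    "fold": math.exp(2.0 * slope),
                    "n": int(len(df)),
                    "outliers_removed": n_out,
                    "excluded": False,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)


def _empty_row(snp, gene, n, n_out, reason) -> dict:
    return {
        "snp_id": snp, "gene": gene, "slope": np.nan, "se": np.nan, "t": np.nan,
        "p": np.nan, "neg_log10_p": np.nan, "fwer": np.nan,
        "neg_log10_fwer": np.nan, "fold": np.nan, "n": n,
        "outliers_removed": n_out, "excluded": True, "reason": reason,
    }
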