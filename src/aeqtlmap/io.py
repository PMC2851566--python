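"""Tables and readers/writers for genotype, allelic-ratio and Ct data.

Conventions
-----------
* Genotypes are coded-allele counts 0/1/2 with NaN for missing; the coded
  allele is ``allele_b`` (the VCF ALT) and the convention is stored in the
  SNP metadata, never implied.
* Allelic ratios are peak-area ratios allele1/allele2 (> 0).  The normalized
  log ratio I uses the natural log throughout; fold changes are reported by
  exponentiation.
* ΔCt = mean target Ct − mean of the three reference-gene Cts; log relative
  expression is −ΔCt·ln 2 under 100% amplification efficiency.

TSV schemas (headers required)
------------------------------
genotypes      wide: ``individual_id`` then one column per SNP (0/1/2/NA)
AER            long: ``individual_id, marker_id, template, replicate, ratio``
Ct             long: ``individual_id, gene, replicate, ct_target, ct_b2m,
               ct_gapd, ct_hprt1``
covariates     ``individual_id, age, sex, ethnicity``
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

ETHNICITY_CATEGORIES = (
    "Cape mixed-ancestry",
    "black African",
    "white",
    "Indian",
    "other",
)

__all__ = [
    "GenotypeTable",
    "NormalizationFactors",
    "DataError",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_aer_measurements",
    "aggregate_replicates",
    "compute_normalization",
    "normalize_aer",
    "delta_ct",
    "qc_filter",
    "ETHNICITY_CATEGORIES",
    "LN2",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeTable:
    """Unphased genotype calls plus SNP metadata.

    ``calls``: DataFrame indexed by individual id, one column per SNP,
    values in {0, 1, 2, NaN} counting the coded allele.
    ``snps``: DataFrame indexed by snp id with columns ``chrom``, ``pos``,
    ``allele_a``, ``allele_b``; the coded allele is ``allele_b``.
    ``cohorts``: optional Series mapping individual id -> cohort label.
    """

    calls: pd.DataFrame
    snps: pd.DataFrame
    cohorts: pd.Series | None = None
    coded_allele: str = "allele_b"

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DataError("genotype calls must be 0, 1, 2 or missing")
        extra = set(self.calls.columns) - set(self.snps.index)
        if extra:
            raise DataError(f"SNPs without metadata: {sorted(extra)[:5]}")

    @property
    def individuals(self) -> list:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    def subset_cohort(self, cohort: str) -> "GenotypeTable":
        if self.cohorts is None:
            raise DataError("no cohort labels attached")
        ids = self.cohorts.index[self.cohorts == cohort]
        return GenotypeTable(
            calls=self.calls.loc[self.calls.index.intersection(ids)],
            snps=self.snps,
            cohorts=self.cohorts.loc[self.cohorts == cohort],
        )

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per individual."""
        return self.calls.notna().mean(axis=1)

    def maf(self) -> pd.Series:
        """Minor-allele frequency per SNP (folded to [0, 0.5])."""
        p = self.calls.mean(axis=0, skipna=True) / 2.0
        return np.minimum(p, 1.0 - p)

    def coded_freq(self) -> pd.Series:
        return self.calls.mean(axis=0, skipna=True) / 2.0


@dataclass
class NormalizationFactors:
    """gDNA-derived multiplicative correction per assay.

    ``strategy`` is ``population-mean`` (one factor per assay, the mean over
    gDNA heterozygotes) or ``per-individual`` (each individual's own gDNA
    ratio).  Factors are strictly positive.
    """

    strategy: str
    factors: pd.DataFrame  # columns: marker_id [, individual_id], nf
    n_gdna: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def lookup(self, individual, marker) -> float:
        if self.strategy == "population-mean":
            row = self.factors[self.factors["marker_id"] == marker]
            if row.empty:
                raise DataError(f"no normalization factor for assay {marker!r}")
            return float(row["nf"].iloc[0])
        row = self.factors[
            (self.factors["marker_id"] == marker)
            & (self.factors["individual_id"] == individual)
        ]
        if row.empty:
            raise DataError(
                f"no per-individual gDNA factor for {individual!r} at {marker!r}"
            )
        return float(row["nf"].iloc[0])


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(
    path: str | Path,
    fmt: str = "tsv",
    snps: pd.DataFrame | None = None,
    cohorts: pd.Series | None = None,
) -> GenotypeTable:
    """Read a genotype table from wide TSV or a minimal VCF.

    TSV: first column ``individual_id``, remaining columns SNP ids, values
    0/1/2 or NA.  VCF: GT-only biallelic records; ``./.`` maps to missing and
    genotypes count the ALT allele.  Triallelic records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
        if "individual_id" not in df.columns:
            raise DataError(f"{path}: missing 'individual_id' column")
        df = df.set_index("individual_id")
        bad = df.notna() & ~df.isin([0, 1, 2])
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise DataError(
                f"{path}: invalid genotype {df.iat[r, c]!r} at data line "
                f"{r + 2}, column {df.columns[c]!r}"
            )
        calls = df.astype(float)
        if snps is None:
            snps = pd.DataFrame(
                {
                    "chrom": "9",
                    "pos": np.arange(1, calls.shape[1] + 1),
                    "allele_a": "A",
                    "allele_b": "G",
                },
                index=calls.columns,
            )
        return GenotypeTable(calls=calls, snps=snps, cohorts=cohorts)
    if fmt == "vcf":
        return _read_vcf(path, cohorts=cohorts)
    raise DataError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path, cohorts: pd.Series | None = None) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, meta, columns = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(
                f"{path}: record {var.ID or var.POS} is not biallelic "
                f"(ALT={var.ALT})"
            )
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        snp_ids.append(snp_id)
        meta.append(
            {"chrom": var.CHROM, "pos": var.POS, "allele_a": var.REF, "allele_b": var.ALT[0]}
        )
        columns.append(col)
    calls = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="individual_id"),
        columns=snp_ids,
    )
    snps = pd.DataFrame(meta, index=snp_ids)
    return GenotypeTable(calls=calls, snps=snps, cohorts=cohorts)


def write_genotypes_tsv(table: GenotypeTable, path: str | Path) -> None:
    out = table.calls.copy()
    out.index.name = "individual_id"
    # keep integers readable in the text file
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def write_genotypes_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only, unphased, 1-based positions)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    inds = table.individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##source=aeqtlmap\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in inds)
            + "\n"
        )
        order = table.snps.loc[table.snp_ids].sort_values(["chrom", "pos"]).index
        for snp in order:
            rec = table.snps.loc[snp]
            calls = table.calls[snp]
            gts = "\t".join(
                gt_map.get(float(v), "./.") if pd.notna(v) else "./." for v in calls
            )
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{snp}\t{rec['allele_a']}\t"
                f"{rec['allele_b']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_aer_measurements(path: str | Path) -> pd.DataFrame:
    """Read a long-format allelic-ratio measurement table.

    Columns: ``individual_id, marker_id, template, replicate, ratio``;
    ``template`` is ``cDNA`` or ``gDNA``; ratios must be positive.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "marker_id", "template", "replicate", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if (df["ratio"] <= 0).any():
        bad = df.index[df["ratio"] <= 0][0]
        raise DataError(f"{path}: non-positive ratio at data line {bad + 2}")
    if not df["template"].isin(["cDNA", "gDNA"]).all():
        raise DataError(f"{path}: template must be 'cDNA' or 'gDNA'")
    return df


# ---------------------------------------------------------------------------
# replicate aggregation & normalization


def aggregate_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean ratio and its standard error per (individual, marker, template).

    Replicate ratios are averaged on the ratio scale (the assay's native
    readout) before any log transform.  A single replicate yields an
    undefined SE (NaN) and is flagged; records whose replicates are all
    missing are dropped with a log entry.
    """
    df = measurements.dropna(subset=["ratio"])
    dropped = set(
        map(
            tuple,
            measurements.loc[
                measurements["ratio"].isna(), ["individual_id", "marker_id", "template"]
            ].itertuples(index=False),
        )
    ) - set(map(tuple, df[["individual_id", "marker_id", "template"]].itertuples(index=False)))
    for key in sorted(dropped):
        logger.info("aggregate_replicates: dropping %s (all replicates missing)", key)
    grouped = df.groupby(["individual_id", "marker_id", "template"], sort=True)["ratio"]
    out = grouped.agg(
        mean_ratio="mean",
        se=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else np.nan,
        n_replicates="count",
    ).reset_index()
    out["single_replicate"] = out["n_replicates"] == 1
    return out


def compute_normalization(
    gdna: pd.DataFrame, strategy: str = "population-mean"
) -> NormalizationFactors:
    """Normalization factors from gDNA heterozygote measurements.

    gDNA amplifies the two alleles equimolarly, so its mean ratio per assay
    estimates the assay's multiplicative bias.  ``gdna`` is an aggregated
    table (from :func:`aggregate_replicates`) restricted to gDNA template.
    """
    if strategy not in ("population-mean", "per-individual"):
        raise DataError(f"unknown normalization strategy {strategy!r}")
    g = gdna[gdna["template"] == "gDNA"] if "template" in gdna.columns else gdna
    if g.empty:
        raise DataError("no gDNA measurements supplied")
    if strategy == "population-mean":
        fac = (
            g.groupby("marker_id")["mean_ratio"]
            .mean()
            .rename("nf")
            .reset_index()
        )
        n = g.groupby("marker_id")["mean_ratio"].count()
    else:
        fac = g[["individual_id", "marker_id", "mean_ratio"]].rename(
            columns={"mean_ratio": "nf"}
        )
        n = g.groupby("marker_id")["mean_ratio"].count()
    if (fac["nf"] <= 0).any():
        raise DataError("non-positive normalization factor")
    return NormalizationFactors(strategy=strategy, factors=fac, n_gdna=n)


def normalize_aer(
    cdna: pd.DataFrame,
    factors: NormalizationFactors,
    marker_genes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Normalize cDNA mean ratios by the gDNA factors; I = ln(normalized).

    ``cdna`` is an aggregated table restricted to cDNA template.  Output
    columns: ``individual_id, marker_id, gene, norm_ratio, log_ratio, se, n_replicates``.
    """
    c = cdna[cdna["template"] == "cDNA"] if "template" in cdna.columns else cdna
    rows = []
    for rec in c.itertuples(index=False):
        nf = factors.lookup(rec.individual_id, rec.marker_id)
        if rec.mean_ratio <= 0:
            raise DataError(
                f"non-positive cDNA ratio for {rec.individual_id} at {rec.marker_id}"
            )
        norm = rec.mean_ratio / nf
        rows.append(
            {
                "individual_id": rec.individual_id,
                "marker_id": rec.marker_id,
                "gene": (marker_genes or {}).get(rec.marker_id, ""),
                "norm_ratio": norm,
                "log_ratio": math.log(norm),
                "se": getattr(rec, "se", np.nan),
                "n_replicates": getattr(rec, "n_replicates", np.nan),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# total expression


def delta_ct(ct: pd.DataFrame, efficiency: float = 1.0) -> pd.DataFrame:
    """Comparative-Ct relative expression per individual and target gene.

    ΔCt = mean(target Ct) − mean(reference Ct over B2M, GAPD, HPRT1);
    log relative expression = −ΔCt·ln(1+efficiency).  Records missing any
    reference gene are excluded with a log entry.
    """
    ref_cols = ["ct_b2m", "ct_gapd", "ct_hprt1"]
    required = {"individual_id", "gene", "ct_target", *ref_cols}
    missing = required - set(ct.columns)
    if missing:
        raise DataError(f"Ct table missing columns {sorted(missing)}")
    rows = []
    for (ind, gene), grp in ct.groupby(["individual_id", "gene"], sort=True):
        if grp[ref_cols].isna().any().any() or grp["ct_target"].isna().any():
            logger.info("delta_ct: excluding (%s, %s): missing Ct values", ind, gene)
            continue
        mean_target = grp["ct_target"].mean()
        mean_ref = grp[ref_cols].to_numpy().mean()
        dct = mean_target - mean_ref
        rows.append(
            {
                "individual_id": ind,
                "gene": gene,
                "delta_ct": dct,
                "log_expr": -dct * math.log(1.0 + efficiency),
                "n_replicates": len(grp),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotyping QC


def hwe_chi2(n_ref: int, n_het: int, n_alt: int) -> tuple[float, float]:
    """One-df chi-square goodness of fit to Hardy-Weinberg proportions."""
    n = n_ref + n_het + n_alt
    if n == 0:
        return np.nan, np.nan
    p = (2 * n_alt + n_het) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_ref, n_het, n_alt], dtype=float)
    keep = exp > 0
    chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    table: GenotypeTable,
    min_call_rate: float = 0.8,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeTable, dict]:
    """Genotyping QC: drop low-call-rate individuals, flag HWE failures.

    Individuals with call rate below ``min_call_rate`` are removed.  Per-SNP
    Hardy-Weinberg chi-square tests run within each cohort (or overall when
    no cohorts are attached); failing SNPs are flagged in the report, not
    removed.  All actions are logged.
    """
    cr = table.call_rate()
    excluded = list(cr.index[cr < min_call_rate])
    for ind in excluded:
        logger.info("qc: excluding individual %s (call rate %.2f)", ind, cr[ind])
    kept = table.calls.drop(index=excluded)
    cohorts = table.cohorts.drop(index=excluded, errors="ignore") if table.cohorts is not None else None
    filtered = GenotypeTable(calls=kept, snps=table.snps, cohorts=cohorts)

    groups: list[tuple[str, pd.DataFrame]]
    if cohorts is not None:
        groups = [(str(c), kept.loc[cohorts.index[cohorts == c].intersection(kept.index)])
                  for c in cohorts.unique()]
    else:
        groups = [("all", kept)]
    hwe_rows = []
    for cohort, calls in groups:
        for snp in calls.columns:
            col = calls[snp].dropna()
            counts = (
                int((col == 0).sum()),
                int((col == 1).sum()),
                int((col == 2).sum()),
            )
            chi2, p = hwe_chi2(*counts)
            flagged = bool(p < hwe_alpha) if np.isfinite(p) else False
            if flagged:
                logger.info(
                    "qc: SNP %s fails HWE in cohort %s (chi2=%.2f, p=%.2e)",
                    snp, cohort, chi2, p,
                )
            hwe_rows.append(
                {
                    "snp_id": snp,
                    "cohort": cohort,
                    "n_ref": counts[0],
                    "n_het": counts[1],
                    "n_alt": counts[2],
                    "hwe_chi2": chi2,
                    "hwe_p": p,
                    "hwe_flagged": flagged,
                }
            )
    report = {
        "excluded_individuals": excluded,
        "call_rates": cr,
        "hwe": pd.DataFrame(hwe_rows),
        "min_call_rate": min_call_rate,
        "hwe_alpha": hwe_alpha,
    }
    return filtered, report
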