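"""Multiple testing, cis-variance decomposition and cross-scan comparisons."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bonferroni_fwer",
    "fwer_thresholds",
    "cis_variance_fraction",
    "compare_scans",
    "direction_concordance",
]


def bonferroni_fwer(p: float, m_tests: int) -> float:
    """Family-wise error rate of a nominal P under Bonferroni correction."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, m_tests * p)


def fwer_thresholds(alpha: float = 0.05, m_tests: int = 56) -> dict:
    """Significance thresholds implied by a Bonferroni FWER level.

    Returns the nominal P threshold alpha/m and its −log10, plus the −log10
    of the FWER level itself, rounded to the reporting granularity used in
    the outputs (2 decimals for −log10 P, 1 for −log10 FWER).
    """
    nominal = alpha / m_tests
    return {
        "alpha": alpha,
        "m_tests": m_tests,
        "nominal_p_threshold": nominal,
        "neg_log10_p_threshold": round(-math.log10(nominal), 2),
        "neg_log10_fwer_threshold": round(-math.log10(alpha), 1),
    }


def cis_variance_fraction(
    log_ratios: np.ndarray,
    log_total_expr: np.ndarray,
    gene: str = "",
    marker_id: str = "",
    scale: str = "allelic",
) -> dict:
    """Proportion of total expression variance attributable to cis effects.

    The per-allele cis variance is estimated from marker heterozygotes'
    normalized log allelic ratios I as sigma2_cis = (1/(2n)) * sum I_i^2:
    under the additivity/independence assumptions (cis and trans act
    additively, do not interact, random mating, no imprinting) I is the
    difference of two independent per-allele cis contributions with mean
    zero, so E[I^2]/2 is the per-allele variance.  The total variance is the
    sample variance of log total expression over all individuals.  With
    ``scale="log-total"`` the alternative factor 1/(4n) is used (variance of
    the mean of the two allele contributions rather than of one allele).

    The fraction is reported even when > 1, flagged as inconsistent.
    """
    I = np.asarray(log_ratios, dtype=float)
    I = I[np.isfinite(I)]
    n = len(I)
    if n < 2:
        raise ValueError("need >= 2 marker heterozygotes with ratios")
    factor = {"allelic": 2.0, "log-total": 4.0}.get(scale)
    if factor is None:
        raise ValueError(f"unknown scale {scale!r}")
    sigma2_cis = float(np.sum(I**2) / (factor * n))
    tot = np.asarray(log_total_expr, dtype=float)
    tot = tot[np.isfinite(tot)]
    if len(tot) < 2:
        raise ValueError("need >= 2 total-expression values")
    sigma2_total = float(np.var(tot, ddof=1))
    fraction = sigma2_cis / sigma2_total
    return {
        "gene": gene,
        "marker_id": marker_id,
        "sigma2_cis": sigma2_cis,
        "sigma2_total": sigma2_total,
        "cis_fraction": fraction,
        "n_heterozygotes": n,
        "n_total": len(tot),
        "inconsistent": fraction > 1.0,
        "scale": scale,
    }


def compare_scans(
    scan_a: pd.DataFrame,
    scan_b: pd.DataFrame,
    effect_col_a: str | None = None,
    effect_col_b: str | None = None,
) -> dict:
    """Pearson correlations of effects and of −log10 P between two scans.

    Scans are joined on ``snp_id`` over non-excluded SNPs; at least three
    shared SNPs are required.  The effect column is ``beta`` for allelic
    scans and ``slope`` for total-expression scans (auto-detected).
    """
    def prep(scan, effect_col):
        s = scan[~scan["excluded"]].copy()
        col = effect_col or ("beta" if "beta" in s.columns else "slope")
        return s.set_index("snp_id")[[col, "neg_log10_p"]].rename(
            columns={col: "effect"}
        )

    a = prep(scan_a, effect_col_a)
    b = prep(scan_b, effect_col_b)
    joined = a.join(b, lsuffix="_a", rsuffix="_b", how="inner").replace(
        [np.inf, -np.inf], np.nan
    ).dropna()
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} shared non-excluded SNPs (need >= 3)")
    r_eff = float(stats.pearsonr(joined["effect_a"], joined["effect_b"]).statistic)
    r_p = float(
        stats.pearsonr(joined["neg_log10_p_a"], joined["neg_log10_p_b"]).statistic
    )
    return {
        "r_effect": r_eff,
        "r_neg_log10_p": r_p,
        "n_shared": int(len(joined)),
        "table": joined.reset_index(),
    }


def direction_concordance(
    scans: dict[str, pd.DataFrame], fwer_threshold: float = 0.05
) -> pd.DataFrame:
    """Direction-of-effect agreement between genes for jointly significant SNPs.

    For each gene pair, SNPs passing the FWER threshold in both scans are
    counted by whether their effects have the same or opposite sign — the
    pattern that distinguishes co-regulation from antisense-style inverse
    regulation.
    """
    if len(scans) < 2:
        raise ValueError("need scans for >= 2 genes")
    rows = []
    for ga, gb in itertools.combinations(sorted(scans), 2):
        a = scans[ga]
        b = scans[gb]
        sig_a = a[(~a["excluded"]) & (a["fwer"] < fwer_threshold)].set_index("snp_id")
        sig_b = b[(~b["excluded"]) & (b["fwer"] < fwer_threshold)].set_index("snp_id")
        shared = sig_a.index.intersection(sig_b.index)
        same = opposite = 0
        for snp in shared:
            ea = float(sig_a.loc[snp, "beta" if "beta" in sig_a.columns else "slope"])
            eb = float(sig_b.loc[snp, "beta" if "beta" in sig_b.columns else "slope"])
            if np.sign(ea) == np.sign(eb):
                same += 1
            else:
                opposite += 1
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "n_shared_significant": len(shared),
                "same_direction": same,
                "opposite_direction": opposite,
            }
        )
    return pd.DataFrame(rows)
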