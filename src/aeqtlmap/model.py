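"""Mixture likelihood for allelic-expression QTL (aeQTL) mapping.

Model
-----
For an individual heterozygous at transcribed marker k of a gene, the log
allelic expression ratio I_k (numerator-allele over the other) is modelled as

    I_k | phase g  ~  Normal( mu_{g,k},  sigma^2_k ),
    mu_{g,k} = sum_i  beta_i * X_ik(g),

where beta_i is the per-copy (natural-log) allelic effect of mapping SNP i
and X_ik(g) in {-1, 0, +1} encodes the phase between SNP i and marker k:
+1 when the coded allele of SNP i lies on the haplotype carrying the marker's
numerator allele, -1 when it lies on the other haplotype, 0 when the
individual is homozygous at SNP i.  Phase is not observed; with posterior
P(g | T) over the phase configurations compatible with the unphased genotype
T (from :mod:`aeqtlmap.phasing`), the likelihood for n individuals is

    L = prod_j  sum_g  P(g | T_j)  prod_k  N(I_jk ; mu_{g,k}, sigma^2_k),

with ratios at different transcribed sites conditionally independent given
the phased genotype.  Maximizing L over (beta, sigma^2) supports single-SNP
tests and adjustment for other SNPs via nested-model likelihood-ratio tests.
Variances are marker-specific but genotype-independent.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeTable
from .phasing import PhasePosterior, em_haplotype_freqs, phase_posteriors

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)

__all__ = [
    "LikelihoodDesign",
    "FitResult",
    "ModelError",
    "IdentifiabilityError",
    "build_phase_indicators",
    "build_design",
    "merge_designs",
    "aer_loglik",
    "fit_mle",
    "lrt",
    "scan_snps",
    "effect_to_fold",
    "stratified_aer",
]


class ModelError(ValueError):
    pass


class IdentifiabilityError(ModelError):
    """A modelled SNP has no informative phase pattern in the data."""


def build_phase_indicators(
    posterior: PhasePosterior,
    snp_ids: list[str],
    marker_ids: list[str],
    numerator_is_coded: dict[str, bool] | None = None,
) -> dict:
    """Per-individual, per-configuration phase indicators X_ik.

    Returns ``{individual: list over configurations of (prob, {marker: X row})}``
    where the X row is an int8 vector over ``snp_ids``.  Markers at which the
    individual is homozygous are absent from the inner dict (no ratio is
    defined there).
    """
    numerator_is_coded = numerator_is_coded or {}
    positions = {s: posterior.snp_ids.index(s) for s in snp_ids}
    marker_pos = {}
    for k in marker_ids:
        if k not in posterior.snp_ids:
            raise ModelError(f"marker {k!r} not in phased subset")
        marker_pos[k] = posterior.snp_ids.index(k)
    out = {}
    for ind in posterior.individuals():
        entries = []
        for (hap_a, hap_b), prob in zip(posterior.configs[ind], posterior.probs[ind]):
            xs = {}
            for k, kp in marker_pos.items():
                if hap_a[kp] == hap_b[kp]:
                    continue  # homozygous at the marker: no ratio
                num_val = 1 if numerator_is_coded.get(k, True) else 0
                if hap_a[kp] == num_val:
                    num, other = hap_a, hap_b
                else:
                    num, other = hap_b, hap_a
                xs[k] = np.array(
                    [num[positions[s]] - other[positions[s]] for s in snp_ids],
                    dtype=np.int8,
                )
            entries.append((float(prob), xs))
        out[ind] = entries
    return out


@dataclass
class LikelihoodDesign:
    """Flattened arrays for vectorized evaluation of the mixture likelihood.

    Rows are (individual, configuration, marker) triples ordered so that the
    rows of one configuration are contiguous and the configurations of one
    individual are contiguous.
    """

    snp_ids: list[str]
    marker_ids: list[str]
    individuals: list
    obs_I: np.ndarray          # (R,) log ratios
    obs_marker: np.ndarray     # (R,) index into marker_ids
    X: np.ndarray              # (R, p)
    cfg_ptr: np.ndarray        # (C,) row start per configuration
    cfg_logp: np.ndarray       # (C,) log P(g|T)
    ind_ptr: np.ndarray        # (J,) configuration start per individual
    cfg_owner: np.ndarray      # (C,) individual index per configuration
    unique_obs: pd.DataFrame   # one row per measured (individual, marker)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def restrict(self, snp_subset: list[str]) -> "LikelihoodDesign":
        """Project the design onto a subset of the modelled SNPs.

        Dropping SNP columns merges configurations that only differed in the
        dropped SNPs' phase, which is exactly marginalization of P(g | T);
        the mixture likelihood of the restricted design equals the likelihood
        of the nested model on the identical individuals, making it safe for
        likelihood-ratio tests.
        """
        cols = [self.snp_ids.index(s) for s in snp_subset]
        return LikelihoodDesign(
            snp_ids=list(snp_subset),
            marker_ids=self.marker_ids,
            individuals=self.individuals,
            obs_I=self.obs_I,
            obs_marker=self.obs_marker,
            X=self.X[:, cols] if self.X.size else self.X.reshape(len(self.obs_I), 0),
            cfg_ptr=self.cfg_ptr,
            cfg_logp=self.cfg_logp,
            ind_ptr=self.ind_ptr,
            cfg_owner=self.cfg_owner,
            unique_obs=self.unique_obs,
        )


def build_design(
    aer: pd.DataFrame,
    posterior: PhasePosterior,
    snp_ids: list[str],
    marker_ids: list[str],
    numerator_is_coded: dict[str, bool] | None = None,
) -> LikelihoodDesign:
    """Assemble the likelihood design from normalized ratios and posteriors.

    ``aer`` needs columns ``individual_id, marker_id, log_ratio``.  Only
    individuals present in the posterior (complete genotypes on the phased
    subset) and heterozygous at >= 1 measured marker enter the design.
    Measurements at markers where the genotype says homozygous raise: a ratio
    is only defined between two distinct alleles.
    """
    indicators = build_phase_indicators(
        posterior, snp_ids, marker_ids, numerator_is_coded
    )
    by_ind: dict[object, dict[str, float]] = {}
    for rec in aer.itertuples(index=False):
        if rec.marker_id in marker_ids:
            by_ind.setdefault(rec.individual_id, {})[rec.marker_id] = float(rec.log_ratio)

    individuals, rows_I, rows_k, rows_X = [], [], [], []
    cfg_ptr, cfg_logp, ind_ptr, cfg_owner = [], [], [], []
    uniq = []
    row = 0
    for ind in posterior.individuals():
        meas = by_ind.get(ind, {})
        if not meas:
            continue
        entries = indicators[ind]
        het_markers = set(entries[0][1])  # same het set in every configuration
        measured = sorted(set(meas) & het_markers)
        extra = set(meas) - het_markers
        if extra:
            raise ModelError(
                f"individual {ind!r} has allelic ratios at {sorted(extra)} "
                "but is homozygous there"
            )
        if not measured:
            continue
        j = len(individuals)
        individuals.append(ind)
        ind_ptr.append(len(cfg_ptr))
        for prob, xs in entries:
            if prob <= 0:
                continue
            cfg_ptr.append(row)
            cfg_logp.append(math.log(prob))
            cfg_owner.append(j)
            for k in measured:
                rows_I.append(meas[k])
                rows_k.append(marker_ids.index(k))
                rows_X.append(xs[k])
                row += 1
        for k in measured:
            uniq.append({"individual_id": ind, "marker_id": k, "log_ratio": meas[k]})
    if not individuals:
        raise ModelError("no individuals with measurable ratios and phase data")
    p = len(snp_ids)
    design = LikelihoodDesign(
        snp_ids=list(snp_ids),
        marker_ids=list(marker_ids),
        individuals=individuals,
        obs_I=np.asarray(rows_I, dtype=float),
        obs_marker=np.asarray(rows_k, dtype=np.int64),
        X=(np.asarray(rows_X, dtype=np.int8)
           if p else np.empty((len(rows_I), 0), dtype=np.int8)),
        cfg_ptr=np.asarray(cfg_ptr, dtype=np.int64),
        cfg_logp=np.asarray(cfg_logp, dtype=float),
        ind_ptr=np.asarray(ind_ptr, dtype=np.int64),
        cfg_owner=np.asarray(cfg_owner, dtype=np.int64),
        unique_obs=pd.DataFrame(uniq),
    )
    return design


def merge_designs(designs: list[LikelihoodDesign]) -> LikelihoodDesign:
    """Concatenate cohort designs for a pooled fit with shared parameters."""
    first = designs[0]
    for d in designs[1:]:
        if d.snp_ids != first.snp_ids or d.marker_ids != first.marker_ids:
            raise ModelError("designs to merge must share SNP and marker sets")
    row_off = np.cumsum([0] + [len(d.obs_I) for d in designs])
    cfg_off = np.cumsum([0] + [len(d.cfg_ptr) for d in designs])
    ind_off = np.cumsum([0] + [d.n_individuals for d in designs])
    return LikelihoodDesign(
        snp_ids=first.snp_ids,
        marker_ids=first.marker_ids,
        individuals=[i for d in designs for i in d.individuals],
        obs_I=np.concatenate([d.obs_I for d in designs]),
        obs_marker=np.concatenate([d.obs_marker for d in designs]),
        X=np.concatenate([np.asarray(d.X).reshape(len(d.obs_I), -1) for d in designs]),
        cfg_ptr=np.concatenate([d.cfg_ptr + o for d, o in zip(designs, row_off)]),
        cfg_logp=np.concatenate([d.cfg_logp for d in designs]),
        ind_ptr=np.concatenate([d.ind_ptr + o for d, o in zip(designs, cfg_off)]),
        cfg_owner=np.concatenate([d.cfg_owner + o for d, o in zip(designs, ind_off)]),
        unique_obs=pd.concat([d.unique_obs for d in designs], ignore_index=True),
    )


def _grouped_logsumexp(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    mx = np.maximum.reduceat(values, starts)
    owner = np.zeros(len(values), dtype=np.int64)
    owner[starts[1:]] = 1
    owner = np.cumsum(owner)
    sums = np.add.reduceat(np.exp(values - mx[owner]), starts)
    return mx + np.log(sums)


def aer_loglik(
    beta: np.ndarray,
    sigma2: np.ndarray,
    design: LikelihoodDesign,
    alpha: np.ndarray | None = None,
) -> float:
    """Log of the phase-mixture likelihood at (beta, sigma^2[, alpha]).

    ``alpha`` holds optional per-marker intercepts (absorbing residual assay
    bias that gDNA normalization missed).  Computed with the log-sum-exp
    trick over phase configurations within each individual.
    """
    beta = np.asarray(beta, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ModelError("sigma^2 must be positive")
    mu = design.X @ beta if beta.size else np.zeros_like(design.obs_I)
    if alpha is not None:
        mu = mu + np.asarray(alpha, dtype=float)[design.obs_marker]
    var = sigma2[design.obs_marker]
    rows = -0.5 * (LOG2PI + np.log(var)) - 0.5 * (design.obs_I - mu) ** 2 / var
    per_cfg = np.add.reduceat(rows, design.cfg_ptr) + design.cfg_logp
    per_ind = _grouped_logsumexp(per_cfg, design.ind_ptr)
    return float(per_ind.sum())


@dataclass
class FitResult:
    """Maximum-likelihood fit of the aeQTL mixture model."""

    loglik: float
    beta: pd.Series
    beta_se: pd.Series
    sigma2: pd.Series
    sigma2_se: pd.Series
    alpha: pd.Series | None
    n_individuals: int
    individuals: frozenset
    n_obs: int
    n_free_params: int
    converged: bool
    n_starts: int = 1
    message: str = ""

    def summary(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"logL = {self.loglik:.4f}  (n={self.n_individuals})"]
        for s in self.beta.index:
            lines.append(
                f"  beta[{s}] = {self.beta[s]: .4f} (SE {self.beta_se[s]:.4f}), "
                f"fold {math.exp(self.beta[s]):.3f}"
            )
        for k in self.sigma2.index:
            lines.append(f"  sigma2[{k}] = {self.sigma2[k]:.4f}")
        return "\n".join(lines)


def _check_identifiability(design: LikelihoodDesign) -> None:
    for i, snp in enumerate(design.snp_ids):
        if design.X.size == 0 or not np.any(design.X[:, i] != 0):
            raise IdentifiabilityError(
                f"SNP {snp!r} has no informative double-heterozygote pattern "
                "(X is identically zero); its effect is not identifiable"
            )


def _null_sigma2(design: LikelihoodDesign) -> np.ndarray:
    """Closed-form MLE of the marker variances when all beta are zero."""
    out = np.empty(len(design.marker_ids))
    for k, marker in enumerate(design.marker_ids):
        vals = design.unique_obs.loc[
            design.unique_obs["marker_id"] == marker, "log_ratio"
        ].to_numpy()
        if len(vals) == 0:
            raise ModelError(f"no observations for marker {marker!r}")
        out[k] = float(np.mean(vals**2))
        if out[k] <= 0:
            out[k] = 1e-8
    return out


def _numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def _marker_obs(design: LikelihoodDesign) -> list[np.ndarray]:
    return [
        design.unique_obs.loc[
            design.unique_obs["marker_id"] == k, "log_ratio"
        ].to_numpy()
        for k in design.marker_ids
    ]


def fit_mle(
    design: LikelihoodDesign,
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-6,
    max_iter: int = 500,
    compute_se: bool = True,
    marker_intercepts: bool = False,
) -> FitResult:
    """Maximize the mixture likelihood over (beta[, alpha], log sigma^2).

    Variances are optimized on the log scale to keep them positive.  The
    default five starts (one at beta = 0 with the closed-form null variances,
    the rest seeded perturbations) guard against multimodality from phase
    ambiguity; the best optimum wins.  A variance collapsing towards zero is
    reported as data degeneracy.  ``marker_intercepts`` adds one free mean
    per marker, absorbing residual assay bias at some cost in power; it must
    match between the models of a likelihood-ratio test.
    """
    p = len(design.snp_ids)
    m = len(design.marker_ids)
    n_obs = len(design.unique_obs)
    per_marker = _marker_obs(design)
    alpha_null = (
        np.array([v.mean() for v in per_marker]) if marker_intercepts else None
    )
    if marker_intercepts:
        sigma2_null = np.maximum(
            np.array([np.mean((v - v.mean()) ** 2) for v in per_marker]), 1e-8
        )
    else:
        sigma2_null = _null_sigma2(design)
    n_extra = m if marker_intercepts else 0

    if p == 0:
        # mixture collapses: every configuration has the same density
        ll = aer_loglik(np.empty(0), sigma2_null, design, alpha_null)
        ses = np.sqrt(2.0 / np.array([len(v) for v in per_marker])) * sigma2_null
        return FitResult(
            loglik=ll,
            beta=pd.Series(dtype=float),
            beta_se=pd.Series(dtype=float),
            sigma2=pd.Series(sigma2_null, index=design.marker_ids),
            sigma2_se=pd.Series(ses, index=design.marker_ids),
            alpha=(pd.Series(alpha_null, index=design.marker_ids)
                   if marker_intercepts else None),
            n_individuals=design.n_individuals,
            individuals=frozenset(design.individuals),
            n_obs=n_obs,
            n_free_params=m + n_extra,
            converged=True,
            message="closed form (null model)",
        )

    _check_identifiability(design)

    def unpack(theta):
        beta = theta[:p]
        alpha = theta[p:p + n_extra] if marker_intercepts else None
        sigma2 = np.exp(theta[p + n_extra:])
        return beta, alpha, sigma2

    def nll(theta: np.ndarray) -> float:
        beta, alpha, sigma2 = unpack(theta)
        return -aer_loglik(beta, sigma2, design, alpha)

    rng = np.random.default_rng(seed)
    base = np.concatenate(
        [np.zeros(p)]
        + ([alpha_null] if marker_intercepts else [])
        + [np.log(sigma2_null)]
    )
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + np.concatenate(
            [rng.normal(0.0, 0.3, size=p),
             rng.normal(0.0, 0.1, size=n_extra),
             rng.normal(0.0, 0.5, size=m)]
        ))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ModelError(f"optimizer failed: {best.message}")
    theta = best.x
    beta_hat, alpha_hat, sigma2 = unpack(theta)
    if np.any(sigma2 < 1e-10):
        raise ModelError(
            "a marker variance collapsed to zero; the data are degenerate "
            "(e.g. noiseless duplicated ratios)"
        )
    beta_se = np.full(p, np.nan)
    sigma2_se = np.full(m, np.nan)
    if compute_se:
        try:
            hess = _numerical_hessian(nll, theta)
            cov = np.linalg.inv(hess)
            d = np.diag(cov)
            if np.all(d > 0):
                se = np.sqrt(d)
                beta_se = se[:p]
                sigma2_se = se[p + n_extra:] * sigma2  # delta method
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    return FitResult(
        loglik=-float(best.fun),
        beta=pd.Series(beta_hat, index=design.snp_ids),
        beta_se=pd.Series(beta_se, index=design.snp_ids),
        sigma2=pd.Series(sigma2, index=design.marker_ids),
        sigma2_se=pd.Series(sigma2_se, index=design.marker_ids),
        alpha=(pd.Series(alpha_hat, index=design.marker_ids)
               if marker_intercepts else None),
        n_individuals=design.n_individuals,
        individuals=frozenset(design.individuals),
        n_obs=n_obs,
        n_free_params=p + m + n_extra,
        converged=bool(best.success),
        n_starts=len(starts),
        message=str(best.message),
    )


def lrt(full: FitResult, null: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested aeQTL models.

    Requires the null to be nested in the full model and both to have been
    fitted on the identical individuals.  Returns (statistic, df, P) with P
    from the chi-square with df = difference in free parameters.
    """
    if null.individuals != full.individuals:
        raise ModelError("LRT models were fitted on different individuals")
    if (full.alpha is None) != (null.alpha is None):
        raise ModelError("LRT models differ in marker-intercept setting")
    df = full.n_free_params - null.n_free_params
    if df < 0 or not set(null.beta.index) <= set(full.beta.index):
        raise ModelError("models are not nested")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df=df))


def effect_to_fold(beta: float) -> float:
    """Fold change implied by an allelic effect.

    Under the additive log-scale model exp(beta) is simultaneously the
    allelic ratio in heterozygotes (per phase unit) and the total-expression
    fold of coded-allele homozygotes relative to the other homozygotes per
    allele copy difference... per the reporting convention used here, the
    minor-homozygote vs major-homozygote total fold equals exp(beta) because
    each of the two alleles changes by beta/allele on the log scale.
    """
    return float(math.exp(beta))


def _informative_heterozygotes(
    calls: pd.DataFrame, snp: str, aer: pd.DataFrame, marker_ids: list[str]
) -> set:
    """Individuals heterozygous at the tested SNP and at >= 1 measured marker."""
    het_snp = set(calls.index[calls[snp] == 1])
    with_marker = set(
        aer.loc[aer["marker_id"].isin(marker_ids), "individual_id"]
    )
    return het_snp & with_marker


def _cohort_groups(genotypes: GenotypeTable) -> list[tuple[str, pd.DataFrame]]:
    if genotypes.cohorts is None:
        return [("all", genotypes.calls)]
    return [
        (str(c), genotypes.calls.loc[
            genotypes.cohorts.index[genotypes.cohorts == c].intersection(
                genotypes.calls.index
            )
        ])
        for c in pd.unique(genotypes.cohorts)
    ]


def _design_for_subset(
    aer: pd.DataFrame,
    genotypes: GenotypeTable,
    snp_ids: list[str],
    marker_ids: list[str],
    numerator_is_coded: dict[str, bool] | None,
    em_tol: float,
) -> LikelihoodDesign:
    """Phase each cohort separately on (markers + SNPs) and pool the designs."""
    subset = list(dict.fromkeys(list(marker_ids) + list(snp_ids)))
    designs = []
    for cohort, calls in _cohort_groups(genotypes):
        usable = calls.dropna(subset=subset, how="any")
        if usable.empty:
            continue
        model = em_haplotype_freqs(usable, subset, cohort=cohort, tol=em_tol)
        post = phase_posteriors(model, usable)
        sub_aer = aer[aer["individual_id"].isin(usable.index)]
        if sub_aer.empty:
            continue
        try:
            designs.append(
                build_design(sub_aer, post, snp_ids, marker_ids, numerator_is_coded)
            )
        except ModelError as err:
            if "no individuals" in str(err):
                continue
            raise
    if not designs:
        raise ModelError("no usable individuals in any cohort")
    return merge_designs(designs) if len(designs) > 1 else designs[0]


def scan_snps(
    aer: pd.DataFrame,
    genotypes: GenotypeTable,
    gene: str,
    marker_ids: list[str],
    snp_ids: list[str],
    adjust: list[str] | None = None,
    numerator_is_coded: dict[str, bool] | None = None,
    min_informative: int = 8,
    m_tests: int | None = None,
    n_starts: int = 5,
    seed: int = 0,
    em_tol: float = 1e-8,
    marker_intercepts: bool = False,
) -> pd.DataFrame:
    """Single-SNP aeQTL scan for one gene, optionally adjusted for other SNPs.

    Each SNP is tested by an LRT of (adjustment set + SNP) against the
    adjustment set alone, fitted on the identical individuals (the nested
    design is the projection of the full design, which marginalizes the phase
    posterior consistently).  SNPs with fewer than ``min_informative``
    informative heterozygotes — heterozygous at the SNP and at >= 1 measured
    transcribed marker — are excluded and flagged.  Bonferroni FWER uses
    ``m_tests`` (default: number of SNPs in the scan list).
    """
    adjust = [s for s in (adjust or [])]
    aer_gene = aer[aer["marker_id"].isin(marker_ids)]
    m = m_tests if m_tests is not None else len(snp_ids)
    rows = []
    for snp in snp_ids:
        pos = (
            float(genotypes.snps.loc[snp, "pos"]) if snp in genotypes.snps.index else np.nan
        )
        base = {
            "snp_id": snp, "gene": gene, "pos": pos,
            "beta": np.nan, "fold": np.nan, "lrt": np.nan, "df": np.nan,
            "p": np.nan, "neg_log10_p": np.nan, "fwer": np.nan,
            "neg_log10_fwer": np.nan, "n_informative": 0,
            "excluded": True, "reason": "",
        }
        if snp in adjust:
            base["reason"] = "in adjustment set"
            rows.append(base)
            continue
        if snp not in genotypes.calls.columns:
            base["reason"] = "not genotyped"
            rows.append(base)
            logger.warning("scan %s: SNP %s absent from genotypes", gene, snp)
            continue
        informative = _informative_heterozygotes(
            genotypes.calls, snp, aer_gene, marker_ids
        )
        base["n_informative"] = len(informative)
        if len(informative) < min_informative:
            base["reason"] = f"<{min_informative} informative heterozygotes"
            rows.append(base)
            continue
        model_snps = adjust + [snp]
        try:
            design = _design_for_subset(
                aer_gene, genotypes, model_snps, marker_ids,
                numerator_is_coded, em_tol,
            )
            full = fit_mle(design, n_starts=n_starts, seed=seed, compute_se=False,
                           marker_intercepts=marker_intercepts)
            null = fit_mle(
                design.restrict(adjust), n_starts=n_starts, seed=seed,
                compute_se=False, marker_intercepts=marker_intercepts,
            )
            stat, df, p = lrt(full, null)
        except (ModelError, IdentifiabilityError) as err:
            base["reason"] = f"fit failed: {err}"
            rows.append(base)
            continue
        beta = float(full.beta[snp])
        fwer = min(1.0, m * p)
        rows.append({
            **base,
            "beta": beta, "fold": effect_to_fold(beta),
            "lrt": stat, "df": df, "p": p,
            "neg_log10_p": -math.log10(p) if p > 0 else np.inf,
            "fwer": fwer,
            "neg_log10_fwer": -math.log10(fwer) if fwer > 0 else np.inf,
            "excluded": False, "reason": "",
        })
    out = pd.DataFrame(rows)
    # rank by significance; ties broken by genomic position
    out = out.sort_values(
        ["excluded", "p", "pos"], ascending=[True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def top_snp(scan: pd.DataFrame) -> str | None:
    """Most significantly associated non-excluded SNP (position-tie-broken)."""
    ok = scan[~scan["excluded"]]
    if ok.empty:
        return None
    return str(ok.iloc[0]["snp_id"])


def stratified_aer(
    aer: pd.DataFrame,
    genotypes: GenotypeTable,
    marker_id: str,
    conditioning_snp: str,
    gdna: pd.DataFrame | None = None,
) -> dict:
    """Marker-heterozygote AER stratified by genotype at another SNP.

    A diagnostic mirroring direct inspection of allelic imbalance: the
    normalized ratios of individuals heterozygous at the transcribed marker
    are grouped by their genotype class at the conditioning SNP, and the two
    largest classes are compared with a two-sided Mann-Whitney test.  The
    gDNA reference column (mean normalized ratio ~ 1 under population
    normalization) is reported alongside when provided.
    """
    sub = aer[aer["marker_id"] == marker_id]
    calls = genotypes.calls
    if conditioning_snp not in calls.columns:
        raise ModelError(f"conditioning SNP {conditioning_snp!r} not genotyped")
    merged = sub.merge(
        calls[conditioning_snp].rename("geno"),
        left_on="individual_id", right_index=True,
    ).dropna(subset=["geno"])
    groups = {
        int(g): grp["norm_ratio"].to_numpy()
        for g, grp in merged.groupby("geno", sort=True)
    }
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    sizes = {g: int(len(v)) for g, v in groups.items()}
    p = np.nan
    eligible = [g for g, v in groups.items() if len(v) >= 2]
    if len(eligible) >= 2:
        two = sorted(eligible, key=lambda g: sizes[g], reverse=True)[:2]
        a, b = groups[two[0]], groups[two[1]]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0  # identical constant groups: no evidence of difference
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    result = {
        "marker_id": marker_id,
        "conditioning_snp": conditioning_snp,
        "group_means": means,
        "group_sizes": sizes,
        "mannwhitney_p": p,
    }
    if gdna is not None:
        g = gdna[gdna["marker_id"] == marker_id]
        if not g.empty:
            result["gdna_mean_ratio"] = float(g["norm_ratio"].mean())
    return result
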