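"""Haplotype-frequency estimation and phase posteriors for small SNP subsets.

Allelic-expression mapping needs the relative phase between a transcribed
marker and the mapping SNPs in the current model.  Because only that relative
phase enters the likelihood, phasing is done per analysis on the small subset
(transcribed markers of the gene plus modelled SNPs), with haplotype
frequencies estimated by EM under Hardy-Weinberg equilibrium within each
cohort.  The posterior probability of each phased configuration given the
unphased genotypes, P(g | T), is then read off the fitted frequencies.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeModel",
    "PhasePosterior",
    "em_haplotype_freqs",
    "phase_posteriors",
    "ld_stats",
    "PhasingError",
]


class PhasingError(ValueError):
    """Raised for unphysical inputs or EM failures."""


@dataclass
class HaplotypeModel:
    """Fitted haplotype-frequency model for a SNP subset.

    Haplotypes are rows of a 0/1 matrix over ``snp_ids`` (1 = coded allele).
    Frequencies are nonnegative and sum to one; the log-likelihood trace is
    monotone non-decreasing by construction of the EM.
    """

    snp_ids: list[str]
    haplotypes: np.ndarray          # (H, s) uint8
    freqs: np.ndarray               # (H,)
    n_individuals: int
    n_iter: int
    loglik_trace: np.ndarray
    cohort: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.freqs < -1e-12):
            raise PhasingError("negative haplotype frequency")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise PhasingError("haplotype frequencies do not sum to 1")

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def hap_index(self) -> dict[tuple[int, ...], int]:
        return {tuple(h): i for i, h in enumerate(self.haplotypes)}

    def frequency_of(self, hap: tuple[int, ...]) -> float:
        idx = self.hap_index().get(tuple(hap))
        return 0.0 if idx is None else float(self.freqs[idx])

    def to_dict(self) -> dict:
        return {
            "snp_ids": list(self.snp_ids),
            "cohort": self.cohort,
            "n_individuals": self.n_individuals,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
            "haplotypes": [
                {"alleles": "".join(map(str, h)), "frequency": float(f)}
                for h, f in zip(self.haplotypes, self.freqs)
            ],
        }


@dataclass
class PhasePosterior:
    """Per-individual phase configurations and their posterior probabilities.

    ``configs[ind]`` is a list of ``(hap_a, hap_b)`` tuples (each an allele
    tuple over the model's SNP subset); ``probs[ind]`` the matching P(g | T),
    summing to one per individual.
    """

    snp_ids: list[str]
    configs: dict[object, list[tuple[tuple[int, ...], tuple[int, ...]]]] = field(
        default_factory=dict
    )
    probs: dict[object, np.ndarray] = field(default_factory=dict)

    def individuals(self) -> list:
        return list(self.configs)


def _compatible_pairs(genotype: np.ndarray):
    """Enumerate unordered haplotype pairs consistent with an unphased genotype.

    The allele at the first heterozygous site is pinned to haplotype A, which
    enumerates each unordered pair exactly once (2^(h-1) pairs for h het sites).
    """
    het = np.flatnonzero(genotype == 1)
    base_a = np.where(genotype == 2, 1, 0)
    base_b = base_a.copy()
    if het.size == 0:
        return [(tuple(base_a), tuple(base_b))]
    pairs = []
    free = het[1:]
    for bits in itertools.product((0, 1), repeat=len(free)):
        a = base_a.copy()
        b = base_b.copy()
        a[het[0]] = 1
        b[het[0]] = 0
        for site, bit in zip(free, bits):
            a[site] = bit
            b[site] = 1 - bit
        pairs.append((tuple(a), tuple(b)))
    return pairs


def _genotype_matrix(calls: pd.DataFrame, snp_ids: list[str]) -> pd.DataFrame:
    missing = [s for s in snp_ids if s not in calls.columns]
    if missing:
        raise PhasingError(f"SNPs absent from genotype table: {missing}")
    sub = calls[list(snp_ids)]
    return sub.dropna(axis=0, how="any")


def em_haplotype_freqs(
    calls: pd.DataFrame,
    snp_ids: list[str],
    cohort: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_starts: int = 1,
    seed: int = 0,
) -> HaplotypeModel:
    """EM estimate of haplotype frequencies from unphased genotypes.

    Parameters
    ----------
    calls
        Individuals x SNPs matrix of coded-allele counts (0/1/2, NaN missing).
        Individuals missing any SNP of the subset are excluded from the fit.
    snp_ids
        SNP subset to phase (order defines the haplotype coordinates).
    tol
        Convergence threshold on the maximum absolute frequency change.
    max_iter
        Iteration cap; exceeding it raises with the log-likelihood trace.
    n_starts, seed
        The default single start is the deterministic uniform distribution
        over the 2^s possible haplotypes (no seed sensitivity).  Additional
        starts draw Dirichlet initial frequencies from ``seed`` and the
        highest-likelihood solution wins.

    Under HWE the diplotype probability is ``f_a * f_b`` (times 2 when the
    two haplotypes differ); the E-step distributes each individual over the
    compatible pairs, the M-step re-counts haplotypes.
    """
    snp_ids = list(snp_ids)
    if len(snp_ids) < 1:
        raise PhasingError("empty SNP subset")
    sub = _genotype_matrix(calls, snp_ids)
    n = len(sub)
    if n == 0:
        raise PhasingError("no individuals with complete genotypes for subset")
    s = len(snp_ids)
    haps = np.array(list(itertools.product((0, 1), repeat=s)), dtype=np.uint8)
    hap_idx = {tuple(h): i for i, h in enumerate(haps)}

    # collapse to unique genotype patterns
    patterns, counts = np.unique(sub.to_numpy(dtype=np.int8), axis=0, return_counts=True)
    pair_a, pair_b, pair_pattern, pair_het = [], [], [], []
    for pi, g in enumerate(patterns):
        for a, b in _compatible_pairs(g):
            pair_a.append(hap_idx[a])
            pair_b.append(hap_idx[b])
            pair_pattern.append(pi)
            pair_het.append(a != b)
    pair_a = np.asarray(pair_a)
    pair_b = np.asarray(pair_b)
    pair_pattern = np.asarray(pair_pattern)
    mult = np.where(np.asarray(pair_het), 2.0, 1.0)
    counts = counts.astype(float)

    def _run(init: np.ndarray) -> tuple[np.ndarray, int, list[float]]:
        freqs = init
        trace: list[float] = []
        for n_iter in range(1, max_iter + 1):
            w = mult * freqs[pair_a] * freqs[pair_b]
            per_pattern = np.bincount(pair_pattern, weights=w, minlength=len(patterns))
            if np.any(per_pattern <= 0):
                bad = patterns[per_pattern <= 0][0]
                raise PhasingError(
                    f"genotype pattern {bad.tolist()} has zero likelihood"
                )
            ll = float(np.dot(counts, np.log(per_pattern)))
            if trace and ll < trace[-1] - 1e-9:
                raise PhasingError("EM log-likelihood decreased")  # pragma: no cover
            trace.append(ll)
            resp = w / per_pattern[pair_pattern] * counts[pair_pattern]
            new = np.bincount(pair_a, weights=resp, minlength=len(haps))
            new += np.bincount(pair_b, weights=resp, minlength=len(haps))
            new /= 2.0 * n
            delta = float(np.max(np.abs(new - freqs)))
            freqs = new
            if delta < tol:
                break
        else:
            raise PhasingError(
                f"EM did not converge in {max_iter} iterations; trace tail "
                f"{trace[-3:]}"
            )
        # final log-likelihood at the converged frequencies
        w = mult * freqs[pair_a] * freqs[pair_b]
        per_pattern = np.bincount(pair_pattern, weights=w, minlength=len(patterns))
        trace.append(float(np.dot(counts, np.log(per_pattern))))
        return freqs, n_iter, trace

    inits = [np.full(len(haps), 1.0 / len(haps))]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        inits += [rng.dirichlet(np.ones(len(haps))) for _ in range(n_starts - 1)]
    freqs, n_iter, trace = max(
        (_run(init) for init in inits), key=lambda r: r[2][-1]
    )

    return HaplotypeModel(
        snp_ids=snp_ids,
        haplotypes=haps,
        freqs=freqs,
        n_individuals=n,
        n_iter=n_iter,
        loglik_trace=np.asarray(trace),
        cohort=cohort,
    )


def phase_posteriors(model: HaplotypeModel, calls: pd.DataFrame) -> PhasePosterior:
    """Posterior P(g | T) over phased configurations for each individual.

    Individuals heterozygous at zero or one subset SNP get a single
    configuration with probability 1.  A genotype whose every compatible pair
    has zero estimated frequency is unphaseable and raises, naming the
    individual.
    """
    sub = _genotype_matrix(calls, model.snp_ids)
    hap_idx = model.hap_index()
    post = PhasePosterior(snp_ids=list(model.snp_ids))
    for ind, row in sub.iterrows():
        g = row.to_numpy(dtype=np.int8)
        pairs = _compatible_pairs(g)
        w = np.array(
            [
                (2.0 if a != b else 1.0)
                * model.freqs[hap_idx[a]]
                * model.freqs[hap_idx[b]]
                for a, b in pairs
            ]
        )
        total = w.sum()
        if total <= 0:
            raise PhasingError(
                f"individual {ind!r}: genotype incompatible with fitted "
                "haplotype frequencies (all configurations have probability 0)"
            )
        post.configs[ind] = pairs
        post.probs[ind] = w / total
    return post


def ld_stats(model: HaplotypeModel) -> pd.DataFrame:
    """Pairwise D, D' and r^2 from fitted haplotype frequencies.

    Monomorphic SNPs make the standardized measures undefined; such pairs are
    reported with NaN.
    """
    s = len(model.snp_ids)
    p = model.haplotypes.astype(float).T @ model.freqs  # coded-allele freq per SNP
    rows = []
    for i, j in itertools.combinations(range(s), 2):
        both = float(
            model.freqs[(model.haplotypes[:, i] == 1) & (model.haplotypes[:, j] == 1)].sum()
        )
        d = both - p[i] * p[j]
        denom = p[i] * (1 - p[i]) * p[j] * (1 - p[j])
        if denom <= 0:
            dprime = np.nan
            r2 = np.nan
        else:
            if d >= 0:
                dmax = min(p[i] * (1 - p[j]), (1 - p[i]) * p[j])
            else:
                dmax = min(p[i] * p[j], (1 - p[i]) * (1 - p[j]))
            dprime = np.nan if dmax == 0 else abs(d) / dmax
            r2 = d * d / denom
        rows.append(
            {
                "snp_a": model.snp_ids[i],
                "snp_b": model.snp_ids[j],
                "D": d,
                "Dprime": dprime,
                "r2": r2,
            }
        )
    return pd.DataFrame(rows)
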