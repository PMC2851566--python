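"""Shared fixtures and helpers: small simulated datasets and normalization."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from aeqtlmap.io import aggregate_replicates, compute_normalization, normalize_aer
from aeqtlmap.simulate import SimulationConfig, simulate, single_gene_config


def normalize_dataset(ds, marker_genes=None):
    """Aggregate replicates and gDNA-normalize a simulated dataset.

    Returns (cDNA table with I, gDNA table normalized the same way).
    """
    agg = aggregate_replicates(ds.aer_measurements)
    factors = compute_normalization(agg[agg["template"] == "gDNA"])
    aer = normalize_aer(agg[agg["template"] == "cDNA"], factors, marker_genes)
    gdna = normalize_aer(
        agg[agg["template"] == "gDNA"].assign(template="cDNA"), factors, marker_genes
    )
    return aer, gdna


@pytest.fixture(scope="session")
def single_gene_dataset():
    """One-gene, one-SNP scenario at n=300 with a ln(1.5) cis effect."""
    cfg = single_gene_config(n_individuals=300, beta=math.log(1.5), seed=11)
    ds = simulate(cfg)
    aer, gdna = normalize_dataset(ds, {"marker1": "GENE1"})
    return cfg, ds, aer, gdna


@pytest.fixture(scope="session")
def two_cohort_small_config():
    """Compact two-cohort design used by pipeline smoke tests."""
    haps = ["0000", "0110", "1011", "1100", "0101"]
    return SimulationConfig(
        snp_ids=["s1", "s2", "m1", "m2"],
        haplotypes=haps,
        cohorts=[
            _cohort("P1", 80, [0.35, 0.25, 0.2, 0.15, 0.05]),
            _cohort("P2", 50, [0.4, 0.3, 0.15, 0.1, 0.05]),
        ],
        genes={"G": ["m1", "m2"]},
        cis_effects={"G": {"s1": math.log(1.6)}},
        marker_sd={"m1": 0.15, "m2": 0.15},
        assay_bias={"m1": 1.2, "m2": 0.9},
        seed=5,
    )


def _cohort(name, n, freqs):
    from aeqtlmap.simulate import CohortSpec

    return CohortSpec(
        name=name, n_individuals=n, haplotype_freqs=freqs,
        ethnicity_probs={"white": 1.0},
    )


def brute_force_mixture_loglik(individuals):
    """Exhaustive-enumeration oracle for the phase-mixture likelihood.

    ``individuals`` is a list of per-individual entries
    ``[(prob_g, [(I_k, mu_gk, sigma2_k), ...]), ...]``.  The total likelihood
    is computed by summing the fully-expanded product over every joint
    assignment of one configuration per individual — no log-sum-exp, no
    factorization — so it is an independent check on the per-individual
    mixture implementation.
    """
    import itertools

    total = 0.0
    for joint in itertools.product(*[range(len(ind)) for ind in individuals]):
        term = 1.0
        for ind, gi in zip(individuals, joint):
            prob, obs = ind[gi]
            dens = prob
            for I, mu, s2 in obs:
                dens *= math.exp(-0.5 * (I - mu) ** 2 / s2) / math.sqrt(
                    2 * math.pi * s2
                )
            term *= dens
        total += term
    return math.log(total)
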