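# aeqtlmap

Fine-mapping of cis-regulatory variants from **allelic** and **total** gene
expression.

Most disease-associated SNPs are non-coding and are thought to act by
changing how much of a nearby gene is transcribed, in *cis* (on their own
chromosome).  A cis effect leaves a specific signature: in an individual
heterozygous for a transcribed SNP, the two alleles of the gene are
expressed unequally.  Measuring that **allelic expression ratio (AER)**
compares the two alleles *within* a sample, so trans-acting influences —
age, sex, environment, batch — cancel, giving far more power to detect cis
effects than comparing total expression *between* individuals (eQTL
mapping).  `aeqtlmap` implements both arms and the machinery around them:

* **aeQTL mixture likelihood** (the core).  For individual *j*, let
  *I<sub>jk</sub>* be the natural log of the normalized allelic ratio at
  transcribed marker *k*.  Conditional on the phased genotype *g*,

  *I<sub>jk</sub>* | *g* ~ N( μ<sub>g,k</sub>, σ²<sub>k</sub> ),
  μ<sub>g,k</sub> = Σ<sub>i</sub> β<sub>i</sub> X<sub>ik</sub>(g),

  where β<sub>i</sub> is the per-copy log allelic effect of mapping SNP *i*
  and X<sub>ik</sub>(g) ∈ {−1, 0, +1} encodes whether the coded allele of
  SNP *i* lies on the haplotype carrying the marker's numerator allele.
  Phase is not observed, so the likelihood mixes over phase configurations
  with posterior weights P(g | T) obtained from EM haplotype-frequency
  estimation under Hardy–Weinberg equilibrium (per cohort):

  L = Π<sub>j</sub> Σ<sub>g</sub> P(g | T<sub>j</sub>)
  Π<sub>k</sub> N( I<sub>jk</sub> ; μ<sub>g,k</sub>, σ²<sub>k</sub> ).

  Both transcribed markers of a gene are combined in one fit, which raises
  the number of informative heterozygotes.  SNP effects are tested by
  likelihood-ratio tests of nested models, allowing adjustment for
  already-identified SNPs; significance is controlled by Bonferroni
  family-wise error rate across the SNP panel.
* **eQTL arm**: OLS of log relative expression (comparative-Ct, −ΔCt·ln 2)
  on additive genotype with age/sex/ethnicity covariates and a z-score
  outlier rule.
* **Assay handling**: replicate aggregation, gDNA-based normalization of
  assay bias (population-mean or per-individual), mixing-series linearity
  checks, genotyping QC (call rate, Hardy–Weinberg), D′/r² LD statistics.
* **Variance decomposition**: per-allele cis variance
  σ̂²_cis = (1/2n) Σ I²<sub>i</sub> over marker heterozygotes, reported as a
  fraction of the total variance of log expression.
* **Synthetic-data generator**: two-cohort datasets (admixed lower-LD and
  European-ancestry higher-LD pools), lognormal allele-level expression with
  known cis effects, trans covariates, assay bias and four replicates — with
  an analytic truth record for validation.

## Worked example

Simulate one gene with a single cis SNP (true effect β = ln 1.5, i.e. a
1.5-fold allelic imbalance per coupled copy) at n = 300, normalize the
replicate ratio measurements against gDNA, and scan:

```python
import math
from aeqtlmap.simulate import single_gene_config, simulate
from aeqtlmap.io import aggregate_replicates, compute_normalization, normalize_aer
from aeqtlmap.model import scan_snps
from aeqtlmap.summary import fwer_thresholds

cfg = single_gene_config(n_individuals=300, beta=math.log(1.5), seed=7)
ds = simulate(cfg)

agg = aggregate_replicates(ds.aer_measurements)
factors = compute_normalization(agg[agg["template"] == "gDNA"])
aer = normalize_aer(agg[agg["template"] == "cDNA"], factors, {"marker1": "GENE1"})

scan = scan_snps(aer, ds.genotypes, "GENE1", ["marker1"], ["snp1"], m_tests=1)
print(scan[["snp_id", "beta", "fold", "lrt", "neg_log10_p", "n_informative"]]
      .round(3).to_string(index=False))
```

prints

```
snp_id  beta  fold     lrt  neg_log10_p  n_informative
  snp1 0.392  1.48 210.123       46.889            130
```

The fitted allelic effect β̂ = 0.392 (fold change e^β̂ ≈ 1.48) recovers the
generative 1.5-fold effect from 130 informative heterozygotes — individuals
heterozygous at both the tested SNP and the transcribed marker — with a
likelihood-ratio statistic of 210 (−log₁₀ P ≈ 47).  For a 56-SNP panel the
Bonferroni threshold report

```python
print(fwer_thresholds(alpha=0.05, m_tests=56))
```

gives a nominal P threshold of 8.9×10⁻⁴ (−log₁₀ P = 3.05; −log₁₀ FWER = 1.3).

The full pipeline (simulate → QC → normalize → phase → scan → adjust →
summarize) is available programmatically via
`aeqtlmap.pipeline.run_pipeline` and from the shell:

```bash
aeqtlmap run --out results/study --seed 1
aeqtlmap simulate --out data/ --seed 1
aeqtlmap scan --genotypes data/genotypes.tsv --aer aer_norm.tsv \
    --gene ANRIL --markers rs10965215,rs564398 --out scan.tsv
```

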