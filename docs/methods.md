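# Methods

## The allelic-expression model

The quantity modelled is the natural log of the normalized allelic
expression ratio, I, measured at a transcribed SNP ("marker") of a gene in
a marker heterozygote.  Allele-level mRNA abundance is taken to be
lognormal with a variance that does not differ between alleles, so I is
normal.  Cis-acting mapping SNPs shift the mean of I additively — no
dominance, no interactions — while trans influences act on both alleles
equally and cancel in the ratio.  The mean for phased genotype g is
μ_{g,k} = Σ_i β_i X_ik(g); the variance σ²_k is genotype-independent but
marker-specific, because different assays have different measurement noise.

**Phase coding.**  X_ik(g) ∈ {−1, 0, +1}: +1 when the coded allele of SNP i
sits on the haplotype carrying the marker's numerator allele, −1 when it
sits on the other haplotype, 0 when the individual is homozygous at SNP i.
This concrete coding is normative for this package; any affine recoding of
X only rescales β.  Consequences that the tests exercise: flipping a
marker's numerator-allele orientation negates X and I together and leaves
β̂ unchanged; a monomorphic SNP has X ≡ 0 and is rejected by an
identifiability check rather than silently fitted.

**Phase uncertainty.**  True phase is unknown; unphased genotypes T
determine a posterior P(g | T) over configurations, computed from haplotype
frequencies estimated by EM under HWE within each cohort.  The likelihood
for n individuals is the mixture
L = Π_j Σ_g P(g | T_j) Π_k N(I_jk; μ_{g,k}, σ²_k), with ratios at different
markers conditionally independent given g.  Evaluation uses log-sum-exp
grouped per individual; a ≤5-individual exhaustive-enumeration oracle pins
the implementation to 1e-10.

**Phasing scope.**  Each fit phases only (transcribed markers of the gene)
∪ (SNPs in the current model), not the whole panel: only the relative phase
between modelled SNPs and markers enters X, and the small-subset EM is
exact and fast.  Whole-region phasing would pool information across more
loci; the difference is a second-order change in P(g | T) for individuals
heterozygous at ≥2 modelled loci.  EM defaults: deterministic uniform
initialization (no seed sensitivity), tolerance 1e-8 on the maximum
frequency change, cap 10,000 iterations, monotonicity of the log-likelihood
asserted every iteration.  Individuals missing any subset genotype are
excluded from that fit and logged.

**Fitting and testing.**  (β, log σ²) are maximized with L-BFGS-B from five
starts (one at β = 0 with the closed-form null variances, four seeded
perturbations); the null model without SNPs has the closed form
σ̂²_k = mean(I²_k).  Standard errors come from the numerically
differentiated observed information.  SNPs are tested by the LRT of
(adjustment set + SNP) vs (adjustment set) with χ²₁ reference; both models
are fitted on identical individuals by projecting the full design onto the
nested SNP set, which marginalizes the phase posterior consistently.
Calibration: across 1000 null simulations the rejection rate at α = 0.05
stays inside the binomial 99% CI and the P-values pass a KS uniformity
test (see `tests/test_acceptance.py`).

**Informative heterozygotes.**  A SNP is only tested when at least 8
individuals are heterozygous at it *and* at ≥1 measured transcribed marker
of the gene (configurable `min_informative`); below that the SNP is flagged
and excluded.  Combining both markers per gene enlarges this set, which is
the point of the joint fit.

**A property worth knowing.**  When a tested SNP is in linkage equilibrium
with an unmodelled causal site, its phase posterior is near 50/50 and the
±β mixture can absorb the symmetric spread that the causal site induces in
I, inflating unadjusted associations at truly unlinked SNPs.  This is
inherent to the likelihood, not a defect of the optimizer: the remedy —
used here and mirrored in the sequential-adjustment scan — is to adjust for
the leading SNP(s), after which these spurious associations collapse (the
two-block simulation in the acceptance suite checks exactly this).  For the
same reason cross-scan *effect* correlations computed over an entire panel
are diluted by such shadow effects, while *significance* correlations
remain high.

## Normalization and total expression

Raw measurements are peak-area ratios allele1/allele2 with four replicates.
Replicates are averaged on the ratio scale (the assay's native readout)
before the log transform; at the observed coefficients of variation the
difference from averaging logs is second order (≈ CV²/2).  gDNA contains
the two alleles equimolarly, so the mean gDNA heterozygote ratio per assay
estimates the assay's multiplicative bias; the default population-mean
factor divides every cDNA ratio of that assay (per-individual normalization
is available by flag; the two agree when gDNA ratios are homogeneous).
Normalized gDNA therefore has mean ratio 1.00 by construction — the
self-consistency check in the acceptance suite.  I uses the natural log
throughout; fold changes are exp(β̂), the expression of coded-allele
homozygotes relative to the other homozygotes.

Total expression uses the comparative-Ct method: ΔCt = mean target Ct −
mean of three reference genes (B2M, GAPD, HPRT1), log relative expression
−ΔCt·ln 2 under 100% amplification efficiency (configurable).  ΔCt is
invariant to per-sample loading shifts that move all Cts equally.  The eQTL
arm regresses log expression on 0/1/2 genotype with age, sex and
closed-set categorical ethnicity; singleton categories are merged into
"other" to keep the design full-rank.  The outlier rule — exclude |z| > 3
per gene before fitting — is an algorithmic surrogate for by-eye exclusion
and is configurable; it exists for reproducibility, and the regression
results are insensitive to it on clean simulated data.

## Cis-variance decomposition

Under additivity, independence of cis and trans contributions, random
mating and no imprinting, I is the difference of two independent per-allele
cis contributions with mean zero, so σ̂²_cis = (1/2n) Σ I²_i over the n
marker heterozygotes estimates the per-allele cis variance.  An alternative
factor 1/(4n) — the variance of the mean of the two allele contributions,
appropriate if one wants the cis share on the log-total scale — is
implemented behind `scale="log-total"`; both are validated against the
generator's analytic truth.  The reported fraction divides by the sample
variance of measured log total expression and is flagged (not clipped) if
it exceeds 1.  Two biases are inherent and documented rather than
corrected: marker-level measurement noise adds σ²_k/2 to the numerator, and
conditioning on marker heterozygosity inflates E[I²] when the marker is in
LD with causal sites.  The recovery experiment therefore uses a
linkage-equilibrium scenario with σ_k = 0.1, where the estimator meets a
<20% median relative error at n = 500.

## Multiple testing and reporting

Bonferroni across the m scanned SNPs: FWER = min(1, m·p); the α = 0.05
threshold for m = 56 is a nominal P of 8.9×10⁻⁴, −log₁₀ P 3.05, −log₁₀
FWER 1.3.  Scan outputs report −log₁₀ values to two decimals.  Ties in
scan ranking are broken by genomic position so reruns are deterministic.
Direction-of-effect concordance between genes counts SNPs significant in
both scans by sign agreement — the readout that distinguishes
co-regulation from antisense-style inverse regulation.

## What the generator emulates — and what it does not

The synthetic module mirrors the study design the analysis assumes: two
cohorts (310 admixed-ancestry individuals with a lower-LD haplotype pool
and cohort-specific frequencies; 177 European-ancestry individuals with a
stronger-LD subset of the same pool), a 56-SNP panel in three independent
LD blocks, three genes with two transcribed markers each, lognormal
allele-level expression, trans effects from age/sex/ethnicity plus a
residual, assay-specific multiplicative bias, per-(individual, marker)
assay noise σ_k shared across replicates, and lognormal replicate noise
(CV 5%, four replicates).  The generative model is exactly the analysis
model, so parameter-recovery tests are well-posed; the truth record stores
the per-allele cis variance exactly (the pool is a finite distribution) and
the total variance of measured log expression in closed form (covariate,
pair-enumeration and Ct-noise terms).

Default effect sizes are chosen to echo the locus being emulated: a
1.4-fold effect on the first gene, a 1.33-fold effect plus an inverse
(0.83-fold) effect of the third gene's transcribed SNP on the second gene
(the antisense pattern), and 1.6-/1.2-fold effects on the third gene, whose
markers carry the largest measurement noise (σ_k = 0.25 vs 0.12–0.15).
Trans residual SD 0.65 on the natural-log scale puts the cis share of total
variance near 5–25% per gene, the regime in which allelic mapping clearly
out-powers total-expression mapping.

Not emulated: mass-spectrometry peak shapes, PCR-efficiency curves,
genotyping error, related individuals, population substructure beyond the
two discrete cohorts, imprinting, and multi-allelic cis architecture.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the stated model, not robustness to assay physics or model
misspecification.

## Problem sizes used in tests and the acceptance script

Calibration and recovery experiments run at the scale the questions
require: 1000 null simulations at n = 100 for type-I error and uniformity,
100 replicates at n = 300 (β = ln 1.5, σ_k = 0.2) for β recovery, 100
seeds at n = 500 for cis-fraction recovery, 20 paired simulations at
n = 200 for the power ordering, and one full two-cohort study-scale run
(56 SNPs, 3 genes, one adjustment round) for the end-to-end numbers.  All
randomness is derived from a single seed; every experiment is deterministic
given it.

## Known limitations

* Per-individual measurement SEs from replicates are not propagated into
  the likelihood — the model carries only the marker-level σ²_k.
* Combined-cohort fits share β and σ²_k across cohorts (pooled likelihood
  with cohort-specific phase posteriors); a meta-analytic alternative is
  not implemented.
* The EM phases small SNP subsets per model rather than the whole region.
* Bonferroni ignores the strong positive dependence among tests in LD, so
  FWER control is conservative.
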