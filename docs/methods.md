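# Methods

This note documents the statistical models implemented in `teqtl`, the
choices made where the design was genuinely open, and what the synthetic
cohorts that back the test suite do and do not emulate.

## Study design

The package targets a paired cohort: each patient contributes one normal
and one tumor expression profile, and a single germline genotype shared
by both samples. Molecular phenotypes are genes and individual
transposable-element (TE) loci quantified from uniquely mapped RNA-seq
reads. All association analyses run separately per tissue except the
tissue-specificity stage, which models both tissues jointly.

## Expression preparation

**Filters.** A phenotype is kept when at least one sample has ≥ 20 reads
*and* its total count reaches the number of samples; these two filters
are applied to the pooled normal+tumor samples (the per-tissue
alternative is available via `pool_tissues=False`). Features with more
than 50% zero samples in a tissue are then dropped per tissue, and the
final feature set is the **union** of the per-tissue survivors — a
feature silenced in tumor but expressed in normal stays in both tables
so cross-tissue contrasts remain possible. Zeros count as "missing" only
for this 50% rule; everywhere else they are ordinary counts.

**Normalization.** Library sizes are per-sample sums over *gene* counts
only: genes carry the sequencing-depth signal, while TE counts are
sparse enough to make a TE-inclusive library size unstable. Between-
sample scaling uses the trimmed mean of M-values (TMM): per sample, log2
expression ratios against a reference sample (the one whose upper-
quartile expression fraction is closest to the cohort mean) are trimmed
30% on each side, the average log2 abundances 5% on each side, and the
surviving M-values averaged with inverse approximate-variance weights;
factors are rescaled to geometric mean 1. The implementation reproduces
the standard published TMM algorithm to < 1e-6 (verified against the
reference implementation on a frozen fixture in the test suite). CPM
values are counts divided by (library size × TMM factor) × 1e6.

**Covariates and rank-normalization.** Technical variability is removed
by OLS residualization on an intercept plus covariates (genotype PCs and
top expression PCs); the expression-PC count is chosen by re-running the
eQTL scan over a candidate grid (0, 1, 2, 5, 10, …) and keeping the
count that maximizes discoveries at 5% FDR, ties to the smaller count.
Finally each feature is mapped to normal quantiles Φ⁻¹((rank − 0.5)/n)
with average ranks for ties. The (rank − 0.5)/n offset was chosen over
the Blom offset ((rank − 3/8)/(n + 1/4)); at the cohort sizes involved
the difference is far below statistical resolution.

## cis-eQTL mapping

Per phenotype, every variant within ±1 Mb (inclusive) of the TSS
(strand-aware: first covered base for `+`, interval end for `-`) is
tested by simple linear regression of the rank-normal phenotype on
dosage; the p-value comes from the t statistic with n − 2 df. The best
hit is the smallest nominal p, ties broken by smaller |TSS distance|,
then lexicographic variant id — determinism where the underlying
procedure is silent.

**Permutation calibration.** The phenotype vector is shuffled across
samples (1,000 times by default) and the whole window re-scanned each
time; the minima of the per-scan p-values form the null. A Beta(k,
n_eff) distribution is fitted to the minima by maximum likelihood
(method-of-moments initialization; L-BFGS-B on the negative
log-likelihood, tolerance 1e-8; moments fallback flagged if the
optimizer fails), and the adjusted p is the Beta CDF at the observed
best p. For m independent variants the minima are Beta(1, m); LD makes
n_eff < m, which is exactly what the fit captures. Per-phenotype
permutation seeds derive from a master seed and a CRC32 hash of the
phenotype id, so results are reproducible under any parallel execution
order.

**FDR.** Genome-wide correction uses Storey q-values: π₀(λ) = #{p >
λ}/(m(1 − λ)) on λ = 0.05…0.95, smoothed with a cubic polynomial and
read off at λ = 0.95, clamped to (0, 1]. Below 100 p-values the
estimator is too noisy and π₀ = 1 (Benjamini–Hochberg behaviour) is
used, flagged.

**Conditional signals.** The per-phenotype nominal threshold is the Beta
quantile of the study-level adjusted-p cutoff (the midpoint between the
largest significant and smallest non-significant adjusted p). The
forward pass repeatedly adds the best passing variant as a covariate and
re-scans (partial correlations, df reduced per covariate); the backward
pass re-tests every variant per signal conditioning on all *other*
signals and keeps the top variant per signal. In the synthetic recovery
studies the adjusted cutoff is set to 1%, which is what the genome-wide
FDR matching typically yields when a minority of phenotypes carries
signal; at a 5% cutoff spurious third signals appear in ~10% of
simulated two-signal phenotypes.

**Replication.** Discovery hits present in a second cohort are re-tested
nominally; π₁ = 1 − π₀ over those p-values estimates the replicated
fraction.

## Tissue specificity

The model for one eQTL over the stacked samples is

    expression ~ dosage + tissue + dosage:tissue + (1 | patient)

and the test is the Wald test of the interaction. Because the design is
exactly balanced (two samples per patient, dosage constant within
patient), the per-patient (mean, difference) transform diagonalizes the
compound-symmetric covariance, and the REML/GLS interaction estimate
*equals* the OLS slope of the within-patient expression difference on
dosage. The default engine computes this closed form (t test, n − 2 df);
a numerical REML mixed-model engine is retained as a cross-check (the
test suite asserts agreement) with a patient-clustered-OLS fallback when
the random-intercept variance collapses. The closed form makes the
thousands of fits in the calibration studies essentially free and has
exact finite-sample df, which is why the type-I error lands inside
[0.035, 0.065] at α = 0.05.

**Classification.** Interaction p-values are FDR-corrected at 5% over
all tested eQTLs ("not significant" means interaction q > 0.05; a
nominal-p variant is available via the `fdr` argument). A significant
interaction marks the eQTL specific to its discovery tissue, except
that when the two tissue slopes share a sign the call additionally
requires the opposite-tissue association to be nominally non-significant
(p > 0.05) — otherwise the eQTL is left unclassified rather than
declared specific on a magnitude difference alone. A non-significant
interaction yields "shared" only when the eQTL is conditionally
significant in both tissues. Every tested eQTL receives exactly one of
the four labels, and swapping the tissue labels swaps
normal_specific ↔ tumor_specific exactly.

**Methylation.** Per eQTL locus the statistic is |median(beta_tumor) −
median(beta_normal)| over samples, averaged over the probes mapped to
the locus (default mapping: probes within ±1 kb of the eQTL variant —
the mapping window is configurable because no canonical choice exists).
Classes are compared with a two-sided Mann–Whitney U test (exact for
small groups, normal approximation above 50 per group as implemented in
scipy).

## Functional enrichment

For each eQTL variant, 100 null variants are sampled uniformly without
replacement from candidates matching |Δ distance-to-TSS| ≤ 2.5 kb and
|ΔMAF| ≤ 0.02 (both inclusive; distance matched on magnitude — the sign
convention is configurable) that were never nominally associated with
any tested phenotype (best p > 0.05). Candidates may be reused across
eQTLs, which avoids pool exhaustion; an eQTL with no eligible candidate
is excluded and logged. Enrichment per peak category is

    fold = (eQTL in-category fraction) / (null in-category fraction)

with a two-sided Fisher exact p on the 2×2 table and Benjamini–Hochberg
correction across categories. Contrasts between runs (TE vs gene eQTLs,
tumor-specific vs shared) are reported as log2 fold ratios per shared
category. Peak intervals follow the BED half-open convention (a 1-based
position p overlaps [start, end) when start < p ≤ end); overlapping
peaks are merged on load.

## Mediation by Bayesian networks

TE–gene association re-uses the permutation machinery with TE expression
in the genotype role (window anchored on the TE start, strand-aware),
q-values at 1% FDR, and per-gene nominal thresholds through the Beta
quantile — all TEs below a significant gene's threshold are reported, so
genes may carry several TEs. Each significant pair is collapsed to its
coordinates on the first principal component of the two standardized
expression vectors, sign-fixed so the gene loading is non-negative, and
rank-normalized; pair-level eQTL mapping at 5% FDR (window = union of
the windows around the TE and the gene TSS) yields (variant, TE, gene)
triplets.

Three Gaussian networks are scored per triplet, each a product of the
variant's marginal and two regressions with maximum-likelihood
variances:

    causal       ll(V) + ll(T|V) + ll(G|T)
    reactive     ll(V) + ll(G|V) + ll(T|G)
    independent  ll(V) + ll(T|V) + ll(G|V)

All three graphs have identical parameter counts (6 regression
parameters + 3 variances), so penalized scores (AIC/BIC) would rank them
identically and the plain likelihood is used. The variant's marginal
term is the same in all three and cancels in the uniform-prior softmax
posteriors (verified exactly in the tests); dosage is treated as a
continuous Gaussian node, as Gaussian-network implementations do.
Posteriors are log-sum-exp stabilized; exact likelihood ties resolve
causal > reactive > independent (and are flagged by the zero-residual
clamp at 1e-12 when they arise from degenerate data).

Tumor triplets are matched to normal triplets sharing the (TE, gene)
pair when the variants are identical or their dosage LD r² ≥ 0.9
(inclusive); duplicate matches keep the highest r². Labels: `no_switch`,
`switch_to_causal` (normal model non-causal, tumor causal),
`switch_to_other`, `unmatched`. A union mode deduplicates the two
tissues' triplets for re-scoring both states.

## Transpochimeric transcripts

A TcGT candidate is a transcript whose strand-aware TSS overlaps a TE
(BED coordinates), whose first exon overlaps no annotated gene exon on
either strand, and which splices into ≥ 1 annotated exon of a gene
through a non-first exon (same strand by default). Candidates are
clustered per target gene by single-linkage on TSS with a 100 bp
inclusive link distance — chains like 1000/1100/1200 form one cluster,
which the phrasing of the aggregation rule permits. Cluster abundance is
the number of distinct samples per group; tumor enrichment is a
one-sided Fisher exact test (tumor > normal), BH-corrected at 5%, with
an optional restriction to (TE, gene) pairs present in a triplet set.

## Synthetic cohorts

The generator emulates the paired design: genotypes are Binomial(2, f)
per patient under Hardy–Weinberg equilibrium with f uniform in the
configured MAF range (default [0.05, 0.5]); expression counts are
negative-binomial (dispersion 0.2 — a standard bulk RNA-seq value; the
generative count model is a package choice, as no canonical one exists)
around exp(baseline + planted effects) scaled by log-normal per-sample
library factors (sd 0.2). Planted cis effects are dosage slopes applied
on the log scale, restricted exactly to their tissue scope — a
normal-only slope contributes nothing to tumor expression by
construction, which makes the interaction-test truth unambiguous.
Phenotype TSSs sit uniformly on one synthetic chromosome; each planted
eQTL's phenotype is re-positioned so the variant falls in the cis
window at a Laplace(50 kb)-distributed offset, mimicking the proximal
decay of real cis effects without claiming its exact distribution.
Triplets are simulated under the three topologies with configurable
slopes and Gaussian noise; methylation betas are Gaussian around 0.5
(clipped to [0, 1]) with a median shift planted only at tumor-specific
loci. Effect sizes are calibration choices, not estimates of real
effect-size distributions.

What the generator does **not** emulate: read-level data and mapping
ambiguity (the central practical difficulty of TE quantification),
tumor clonal heterogeneity and purity variation, LD structure beyond
explicitly constructed proxies, trans effects, and retrotransposition.
Passing tests therefore demonstrate that the *inference chain* is
correct and calibrated under its stated model, not that the pipeline is
robust to every artifact of real tumor RNA-seq.

## Problem sizes in the acceptance studies

The test suite and `scripts/acceptance.py` scale the simulations to a
single CPU: beta-approximation fidelity uses 200 null phenotypes × 100
variants × 10,000 permutations (the script uses 120 × 5,000); FDR
calibration 20 studies × 1,000 null phenotypes at 300 permutations (the
script uses 20 × 250); conditional recovery 100 seeds (script 60);
topology recovery 300 triplets per topology at n = 275, slopes 0.5,
noise sd 1; tissue-specificity 300 planted eQTLs per class
plus 1,000 null interaction tests; enrichment 500 eQTLs × 100 matched
nulls against peaks covering 10% of a 10 Mb chromosome; π₁ on 5,000
replication pairs with a true fraction of 0.7. Seeds are fixed in the
tests and derived from `--seed` in the script.

## Known limitations

- The Beta fit assumes the permutation minima are exchangeable across
  permutations; grouped-phenotype permutation schemes are out of scope.
- The conditional pass controls the FDR only through the per-phenotype
  threshold; it does not re-permute conditionally.
- The q-value smoother uses a cubic polynomial on the λ grid rather than
  a smoothing spline; on 19 grid points the two are practically
  indistinguishable, but exact numerical agreement with spline-based
  implementations is not guaranteed.
- Dosages are never covariate-adjusted; covariates are removed from
  phenotypes only.
- The BGe-style marginal-likelihood scorer for networks is not
  implemented; with equal parameter counts across the three topologies
  the maximum-likelihood score already yields the same ranking in the
  regimes tested.
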