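# Methods

`polyherit` partitions the polygenic signal and SNP-heritability of a binary
disease across exclusive genomic compartments (genic coding, genic
noncoding, intergenic) and cell-type regulatory annotations, and provides
the surrounding enrichment machinery: polygenic risk scores over discovery
P-value thresholds, multi-component GREML with a liability-scale transform,
matched-null SNP permutation tests, locus-by-cell-type clustering, and a
degree-aware protein-interaction connectivity test.  Everything runs on
synthetic cohorts with known ground truth, so every stage is testable
without access to real genotype or epigenome data.

## The generative model

**Genotypes.**  Dosages (0–2) are produced by thresholding two latent
Gaussian haplotypes per individual.  Within an LD block of `ld_block_size`
SNPs (default 20) the latents share an exchangeable correlation
`within_block_rho`; a haplotype carries the minor allele when its latent
falls below `Φ⁻¹(MAF)`, so per-SNP allele frequencies (drawn uniformly from
`maf_range`, default 0.05–0.5) are honoured in expectation while inter-SNP
r² inside a block is tunable through one parameter.  Blocks are
independent, which is the simplest structure exposing r²-based operations
(LD expansion of lead SNPs, LD-buddy counts) to non-trivial input.  SNP
positions are distinct uniform draws on a genome of 1 kb per SNP.

**Disease.**  Liability = Σⱼ bⱼ zⱼ + ε with zⱼ the standardized genotype,
ε ~ N(0, 1 − h²), and bⱼ ~ N(0, h²_c / M_c) for SNPs in compartment c
(Gaussian-within-annotation, i.e. infinitesimal inside each compartment;
SNPs in compartments with h²_c = 0 have exactly zero effect).  Effects are
rescaled against a reference population draw so each compartment
contributes its configured liability-variance share exactly, removing
effect-sampling noise from recovery experiments.  An individual is a case
iff liability > Φ⁻¹(1 − K); the default prevalence K = 0.06.  Ascertained
(case-enriched) cohorts are built by rejection sampling from the population
until the case and control quotas fill, emulating roughly balanced
case-control GWAS designs.

**Genome fixture.**  Genes (5–50 kb, 1–4 coding subintervals, random
strand) are packed without overlap by Dirichlet-distributed gaps; an
infeasible packing raises an error naming the constraint.  Per
(histone mark, cell type) peak tracks place ~1.5 kb peaks preferentially
(90%) inside genic territory; a fraction `peak_sharing` of each mark's
peaks is shared identically by all cell types, the remainder placed
independently per cell type, so `peak_sharing=1` yields identical tracks
and `peak_sharing=0` yields independent tracks whose base-level Jaccard is
d/(2−d) at coverage d.  The PPI graph is Barabási–Albert preferential
attachment (m=2), giving the heavy-tailed degree distribution the
degree-binned permutation needs.  Conservation scores follow a
0.85·N(0,2) + 0.15·N(7,1.5) mixture so a "score < 5" baseline filter is
meaningful.

What the generator deliberately does not emulate: realistic human LD maps
and recombination hotspots, empirical allele-frequency spectra, imputation
error structure, population stratification, and any coupling between PPI
topology and causal effects.  Tests passing on these cohorts demonstrate
correctness and calibration of the machinery, not performance on real data.

## Coordinates

All intervals are half-open `[start, end)`; a SNP at position p overlaps an
interval iff `start ≤ p < end` (positions compared directly on the interval
axis).  Genic windows are boundary-inclusive: with a ±10 kb window a SNP
exactly 10 kb from the outermost covered base of a gene is still genic.
Compartments are exclusive with precedence coding > genic noncoding >
intergenic.  Locus-to-gene windows run 110 kb upstream of the TSS to 40 kb
downstream of the TES, orientation flipped for minus-strand genes,
boundaries inclusive.

## Association and polygenic scores

The discovery scan is per-SNP additive logistic regression (Wald test) with
covariates, solved by a dedicated Newton–Raphson routine (cross-checked
against statsmodels); monomorphic or separated SNPs are flagged missing.
QC applies the conventional thresholds: sample call rate ≥ 0.95, SNP call
rate ≥ 0.98, HWE P ≥ 1e-6, MAF ≥ 1% (genotyped) / 0.5% (imputed),
imputation info ≥ 0.5.

The risk score for individual i is PRSᵢ = Σⱼ βⱼ dᵢⱼ over SNPs passing the
discovery threshold (strict `<`), with β oriented to the risk allele
(β > 0) and dosage flipped accordingly; this equals unoriented scoring up
to an additive constant.  Evaluation regresses validation phenotype on the
score plus covariates; the null model holds covariates only, so
Nagelkerke's R² = [1 − exp((2/n)(ℓ₀−ℓ₁))]/[1 − exp((2/n)ℓ₀)] isolates the
score.  The threshold grid is 5e-8 … 1 (13 values).  No LD clumping is
applied before scoring.

## Heritability

GRMs follow A_jk = (1/M) Σᵢ (x_ij − 2pᵢ)(x_ik − 2pᵢ)/(2pᵢ(1−pᵢ)) with
sample allele frequencies; monomorphic SNPs are dropped with a warning.
Relatedness pruning greedily removes the individual participating in the
most pairs with A_jk > 0.05 until none remain.

`reml_fit` maximizes the restricted likelihood of y = Xb + Σ_c g_c + e,
g_c ~ N(0, A_c σ²_c), by average-information updates with an initial
Haseman–Elston method-of-moments step (off-diagonal cross-products
regressed on GRM entries) and EM fallback when the AI matrix is singular
(e.g. duplicated components, which are flagged).  Components are
constrained non-negative (floor 1e-6 of the phenotypic variance);
convergence is a restricted log-likelihood change below 1e-6 (max 100
iterations); SEs come from the inverse AI matrix, variance *ratios* and
their SEs by the delta method.  Dropping one component is tested with the
boundary-mixture LRT p = 0.5·Pr(χ²₁ > 2Δℓ).  The fit is validated against
an independent eigendecomposition grid-search oracle (agreement < 1e-3 on
the ratio).

Observed-scale estimates from (ascertained) case-control samples convert to
the liability scale by h²_l = h²_o · K²(1−K)²/(z²P(1−P)), with z the normal
density at the threshold and P the sample case proportion; the multiplier
is linear, so SEs transform identically.  Bookkeeping statistics:
enrichment of variance = (%variance)/(%SNPs); the deviation-from-expected
test is a one-parameter z-test of v_obs against v_total·(SNP fraction),
ignoring uncertainty in the total (the totals are far more precisely
estimated than the components); fixed-effect inverse-variance weighting
combines per-study estimates.

**Known limitation — ascertainment attenuation.**  On case-control samples
ascertained to ~50% cases at K = 0.06 with total liability h² ≈ 0.42, REML
plus the liability transform systematically under-estimates the components
by roughly 20% (measured here across 10 seeds at n = 4000, M = 3000:
mean estimates 0.081/0.201/0.063 for true 0.10/0.25/0.07), even though the
identical machinery is unbiased on the continuous liability.  This is the
well-documented first-order nature of the transform under strong
ascertainment, not an estimation defect; Haseman–Elston/PCGC-style
regression would avoid it but is outside this package's estimator.  The
acceptance suite exposes this honestly: the recovery test on ascertained
cohorts fails for the genic components while the continuous-liability and
oracle checks pass.  Recovery experiments use unlinked SNPs
(`within_block_rho=0`) so that cross-compartment LD tagging does not
confound the attribution.

## Matched-null enrichment

Each query SNP is matched on MAF (±0.05 absolute), LD-buddy count at
r² > 0.5 (±10%), distance to the nearest transcript boundary (±10%), and
gene count within ±500 kb (±10%).  LD buddies are counted within a 100 kb
window via banded correlation passes (exact under block LD).  Null sets
draw one match per query uniformly from its pool, without within-set
duplicates (across-set duplicates allowed); queries with empty pools are
dropped globally and reported; every emitted null is re-verified against
all four criteria at run time.  The empirical p of the observed overlap is
(#null sets strictly greater)/n_sets, matching arithmetic like
4/10,000 = 4e-4; an add-one estimator and a tie-corrected mid-p are also
provided.  Because overlap counts are small integers, the strictly-greater
p is discrete-shifted and only the mid-p is approximately uniform under the
null — calibration studies therefore use the mid-p.

Two named baseline builders reflect two reasonable background definitions:
`near-genic-non-mark` (genic SNPs ≥ 5 kb from every peak) and
`intergenic-nonconserved` (intergenic, conservation < 5, outside all
regulatory elements).  Neither is privileged.

Locus × cell-type overlap matrices use the any-SNP rule (lead or any
r² ≥ 0.8 tag inside the track); rows and columns are ordered by
complete-linkage agglomerative clustering on Euclidean distances, and locus
breadth (row mean) is summarized as counts above 80% and below 20% of cell
types.

## Network connectivity

Direct connectivity is the number of PPI edges joining two seed genes.
The null replaces every seed with a node from the same factor-2 logarithmic
degree bin, sampled without replacement within bins (preserving the seed
set's bin histogram exactly; single-member bins map to themselves with a
warning).  The default p is the add-one estimator
(#{null ≥ obs} + 1)/(n_perm + 1) over 1,000 permutations, since the
observed arrangement is itself one admissible draw; the raw inclusive
fraction is available.

## Problem sizes and numerical choices

Simulation experiments are sized for a single CPU: three-component REML
recovery at n = 4000 individuals / M = 3000 SNPs over 10 seeds; PRS
compartment sweeps at n = 4000 discovery / 2000 validation / M = 2000 over
10 seeds; the matched-null run at 45 queries, 10,000 sets, a 100,000-SNP
universe; calibration studies at 150–200 replicates with n_sets = 500.
Ties in clustering and pruning are broken deterministically (first index);
all generators are `numpy.random.Generator`-seeded and bit-reproducible
under a fixed seed.
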