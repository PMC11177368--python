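# Methods

`equigen` implements the quantitative-genetics workflow used to dissect a
major body-size QTL in a horse breeding cohort: GRM-based variance
components, leave-one-chromosome-out mixed-model association, local
genetic correlations, chromosomal breeding values, and a two-pronged
(LD- and ROH/IBD-based) fine-mapping procedure. Because individual-level
data of such cohorts are not public, the package ships a synthetic-data
generator whose defaults encode the study conditions, and every analysis
stage is validated against planted truth.

## The mixed model

All estimation is built on

    y = X b + sum_c u_c + e,     u_c ~ N(0, s2_c K_c),   e ~ N(0, s2_e I)

where `K_c` is a genomic relationship matrix over a named variant subset
(whole genome, one chromosome, a QTL window, or a leave-one-chromosome-out
set). The GRM estimator is the per-SNP-standardised cross-product
(VanRaden method 1 in its GCTA form),

    A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with `p_i` the sample frequency of the counted (minor) allele and missing
genotypes mean-imputed before centring. The same cross-product expression
is used on the diagonal; the slightly different diagonal estimator of some
tools is an O(1/m) difference and is not replicated. Allele frequencies
always come from the analysis sample itself.

Genotype codes count minor alleles (0/1/2, −1 missing). The minor allele
is fixed once at load time from the file's own sample frequencies and never
re-polarised, so conditional analyses and LD stay on one scale. All
coordinates are 1-based with inclusive endpoints; region arithmetic is in
base pairs.

### REML

Variance components are estimated by average-information REML with one
expectation–maximisation warm-up step (univariate fits). Key numerical
choices:

* convergence when |Δ logL| < 1e-4 (at most 100 iterations), or when the
  likelihood stalls for consecutive iterations at a constrained optimum,
  in which case the best visited state is returned;
* variances constrained to a floor of 1e-6 · V_P ("constrained REML");
  an active-set rule keeps floored parameters out of the Newton step while
  their score points downhill;
* starting values by moment matching — the OLS residual cross-product is
  projected onto span{K_c, I} in the Frobenius inner product (this only
  initialises the iteration; it is never reported as an estimate);
* standard errors from the inverse average-information matrix, with the
  delta method for ratios (h², variance fractions, r_G).

A single-GRM model is solved exactly in the eigenbasis of the GRM (one
eigendecomposition, then O(n) per iteration); multi-component models use
dense iterations with one Cholesky factorisation and inversion per step.

For two traits the observations are stacked and every component carries a
2×2 (co)variance block. Covariances are *unconstrained* during iteration:
the total covariance matrix can remain positive definite even when a
genetic correlation passes ±1 (the residual block keeps the traits
distinguishable), non-PD proposals are caught by step halving, and the
reported r_G is clamped to [−1, 1] post hoc. An in-iteration clamp of the
covariance to the PD cone was tried and rejected: for traits that truly
share a QTL (local r_G = 1) it creates an artificial boundary on which the
AI iteration oscillates indefinitely. Bivariate fits use complete cases
(both traits observed).

The likelihood-ratio test for genetic variance uses the boundary mixture
0.5·χ²₀ + 0.5·χ²₁ when a single variance is dropped (p = 0.5 at LRT = 0)
and a plain χ²_k for k > 1; traits with p > 0.05 are flagged as showing no
usable genetic variance.

### BLUP

Component gEBVs are û_c = s2_c K_c V⁻¹ (y − X b̂) at the REML estimates,
with b̂ the GLS solution — algebraically the mixed-model-equation solution.
The test suite verifies this against an explicit MME solve written for
whitened effects u = L a with K = L L' (a centred GRM is always singular,
so the naive K⁻¹ form of the equations does not exist).

## Association scans

`run_mlm_loco` follows the two-stage MLMA-LOCO strategy: per chromosome,
the null model with the leave-one-chromosome-out GRM is fitted once by
REML; the covariance is eigendecomposed; every SNP on that chromosome is
then tested by a generalised-least-squares Wald test on the rotated data.
Effects are per copy of the minor allele. Variants with missing calls take
an exact GLS path on the observed individuals (the individual is dropped
for that variant only). The genome-wide threshold is Bonferroni
(α / number of tests actually performed), and the inflation factor is the
median association χ² over the χ²₁ median (0.45494).

Conditional scans add the conditioning SNP's dosage (or a conditioning
trait) as a fixed covariate everywhere — including the null fits — and
skip the conditioning SNP itself. Significant variants are clustered into
QTL regions split at gaps > 1 Mb (configurable); the top SNP is the lowest
p-value with ties broken by lowest position, matching how a tied lead SNP
is conventionally reported and conditioned on.

## Runs of homozygosity

The detector reproduces the published scanning-window --homozyg algorithm:
windows of 50 SNPs slide along the region; a window is homozygous if it
has ≤ 3 heterozygous and ≤ 5 missing calls; a SNP is ROH-eligible when the
proportion of overlapping homozygous windows exceeds 0.05; maximal runs of
eligible SNPs are split at inter-SNP gaps > 1000 kb and filtered to ≥ 50
SNPs, ≥ 100 kb, and ≥ 1 SNP per 50 kb. Two points the published parameter
list leaves open were fixed here: the window-hit threshold (0.05, the
cited tool's default) and segment endpoints, which are reported at the
outermost eligible SNPs rather than extended into flanking gaps. A
brute-force re-derivation of these rules serves as the oracle in the test
suite.

Shared-ROH analysis cuts all segments at every boundary, merges adjacent
elementary intervals with identical carrier sets, and reports carrier
counts per group (e.g. top-k vs bottom-k gEBV). A carrier's allele class
is its genotype vector over the interval; classes are compared only over
mutually non-missing SNPs, so missing calls never break equality.

## Consequence annotation

A minimal annotator stands in for the external effect predictor: coding
SNVs are translated through the standard genetic code (reverse-complemented
on minus-strand transcripts) into stop_gained / missense / synonymous
calls; other variants become intron, upstream/downstream (within 100 kb of
a transcript by default, matching the study's setting), or intergenic.
Impact classes: stop_gained→HIGH, missense→MODERATE, synonymous→LOW,
everything else→MODIFIER; a variant's impact is the maximum over
transcripts. Only these terms are implemented (the simulator emits SNVs
only); exonic non-CDS positions fall back to intron_variant since the term
set carries no UTR classes. Gene models are GFF3; because toy chromosomes
are ~120 Mb of empty sequence, the companion FASTA may cover only a slice
per chromosome with the 0-based slice start encoded as `offset=` in the
record description.

## Fine-mapping

The LD prong keeps genome-wide significant variants with r² > 0.8 to the
top SNP(s) — r² is the squared Pearson correlation of minor-allele counts
over mutually non-missing individuals (genotype, not haplotype, r²) — and
restricts them to HIGH/MODERATE impact. The IBD prong ranks individuals by
the QTL-chromosome gEBV component, takes the top-10 and bottom-10, detects
ROH across the span of significant variants ± 100 kb, intersects the top
group's segments (strict all-carrier sharing by default; a share fraction
is exposed), and keeps significant HIGH/MODERATE variants inside those
intervals, also reporting intervals where bottom-group carriers hold a
different allele class. The final report is the intersection of both
shortlists, ranked by p then position, with pairwise r² among finalists.
The IBD prong's premises — shared ROH are IBD, a single founder mutation,
founder-haplotype enrichment in one extreme group, gEBVs ranking better
than phenotypes — are assumptions of the design, enforced as documented
preconditions rather than silently.

## The synthetic cohort

`simulate` generates LD-structured diploid genotypes by a founder-mosaic
(copying) model: per chromosome, 40 founder haplotypes carry alleles drawn
at U-shaped (Beta(0.2, 0.2)) frequencies; each individual haplotype copies
founders with switch points at 1 per Mb (Poisson along the map). A
coalescent simulation would be more realistic demographically; the copying
model was chosen because it directly produces the shared founder segments
the ROH/IBD stage needs, and its block structure is controlled by a single
rate. The cohort has no stated LD-decay profile to match, so the switch
rate is a documented calibration knob, not an estimate.

Defaults encode the study conditions: n = 2000 individuals; three 120-Mb
chromosome-like segments with ~1100 background SNPs each plus ~300 dense
SNPs inside the QTL window; one causal nonsense SNV at 107,558,421 bp on
chromosome "3" at MAF 0.45 adding 2.68 trait units per minor allele; a
height-like trait with mean 167.6, SD 3.6 and h² 0.528; ordinal
conformation scores on −3..+3 (0..+3 for defect traits) via thresholds on
the standardized phenotype. Variants below MAF 0.01 are dropped at
generation (except planted causals).

Causal structure around the QTL: the founder haplotypes carrying the
causal minor allele are identical over ±1 Mb (a single founder mutation),
and individual haplotypes that carry the mutation copy that founder
*unbroken* across the block — switch points do not interrupt it — so
minor-allele homozygotes are homozygous across the block and the ROH
machinery has something real to find. (Without the unbroken segment, a
switch rate of 1/Mb fragments carrier haplotypes faster than the 50-SNP
minimum ROH length at the simulated marker density, and the shared-ROH
step has nothing to intersect.) Non-carrier founders get low
allele-1 frequencies inside the block (Beta(0.2, 0.8)) — the founder
mutation arose on a locally rare haplotype background — which gives the
causal variant a realistic halo of high-r² neighbours.

Phenotypes: fixed part (per-trait structure: an age-in-days slope for
objectively measured traits; age-class, sex, judge and event level effects
for scored traits, drawn once per level at 0.5·SD — 0.25·SD for age class —
and centred) + causal effects + polygenic part + Gaussian residual.
Polygenic and region effects act on *standardized* genotypes — the same
exchangeability assumption GREML makes; effects on raw dosages with a
U-shaped MAF spectrum would make single-GRM heritability recovery fail for
reasons unrelated to the estimator (measured bias ≈ −0.15). The polygenic
part is rescaled so the realized genetic variance hits h²·SD² exactly;
background effects are excluded from causal windows so window truths are
clean.

Two planting parameterisations exist because the source design needs both:
a `CausalVariant` with a per-allele `beta` (GWAS effect recovery), and
region-level variance — `variance_fraction` on a variant, or a
`RegionEffect` spreading exchangeable effects over a window (variance
partitioning). A single large-effect variant is *not* recoverable as a
window-GRM variance share: the GRM model spreads weight 1/m per SNP, and a
one-direction covariance contribution is mostly absorbed elsewhere (window
fraction ≈ 0.07 for a planted 0.171 in our measurements). The
variance-partition studies therefore plant region-level variation, which
is also what "causal variation inside a window" means operationally.

What the generator does not emulate: real demography or pedigree
structure, genotyping or imputation error (the DR2-like `quality` field is
pass-through only), X chromosomes, multi-allelic sites, indels, and
haplotype phasing outside the simulator. Passing tests show the estimators
recover what they model on data satisfying their assumptions — not that
those assumptions hold in any particular livestock cohort.

## Replication studies and problem sizes

`equigen.replication` re-runs the analysis designs end to end on fresh
cohorts: single-GRM h² recovery (true 0.528); five-GRM window partitioning
(6-Mb window at 17.1% with a 14-Mb exclusion buffer, 2-Mb window at 8.7%
with a 4-Mb buffer, rest-of-genome); MLM-LOCO effect recovery at the
causal SNP (true 2.68); QTL-window bivariate r_G for two traits sharing
the planted variant; null-scan calibration (λ); conditional-scan peak
removal; and full fine-mapping recovery of the planted nonsense variant.
All run at n = 2000. `scripts/acceptance.py` uses 10 replicates per
design; the pytest suite runs scaled-down replicate counts (6/5/5/4
replicates, and 10 for the end-to-end recovery rate) so the whole suite
stays fast, with unchanged cohort size and thresholds.

## Known limitations

* The AI-REML path materialises dense n×n (2n×2n bivariate) covariance
  matrices; practical up to a few thousand individuals, not biobank scale.
* Wald tests are asymptotic; no saddlepoint or exact small-sample
  correction, so rare-variant p-values at small n are approximate.
* r² is genotype-dosage correlation, not EM-phased haplotype r²; for pairs
  of rare variants in repulsion the two can differ.
* The annotator handles biallelic SNVs on toy gene models only — no
  splice-region logic, regulatory features, frameshifts, or database
  lookups of known variants.
* PLINK text orientation at MAF exactly 0.5 is a tie; round-tripping
  preserves codes only away from ties.
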