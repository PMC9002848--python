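# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducing
results.

## Data model

Input is a gene × sample matrix of fragment counts (concordant read
pairs) with a sample sheet giving time point (days after planting),
replicate and experiment per library, plus plain-TSV annotation tables:
gene lengths in bp, a flax → Arabidopsis homologue map with a
characterized / unknown-function status per pair, a flowering-gene list of
Arabidopsis ids, TF-family membership and GO assignments.  Gene ids are
opaque strings; gene length comes only from the lengths table (no GFF
computation), and genes absent from the homologue map are
`no_homologue`.  Missing optional annotation files degrade to empty
annotation sets with a warning rather than an error, so partial analyses
remain possible.

## Filtering and normalization

Genes are kept when their mean CPM over the replicates of at least one
time point exceeds 1, computed on raw (pre-TMM) library sizes — the
filter runs before normalization, in the stated order of the original
protocol.  The threshold is strict (`> 1`).

TMM normalization follows the trimmed-mean-of-M-values definition: the
reference library is the sample whose 75th-percentile CPM (after dropping
all-zero genes) is closest to the mean 75th percentile; for each library,
per-gene log2 ratios M against the reference and average log intensities
A are formed over genes expressed in both; the top and bottom 30% of M
and 5% of A are trimmed (the method's published defaults — the protocol
names none); the factor is the weighted mean of the surviving M values
with inverse delta-method binomial variances as weights; factors are
rescaled to geometric mean 1.  Ties in the trimming ranks are averaged.
A library sharing no expressed genes with the reference gets factor 1
with a warning.  During development the implementation was verified to
reproduce an independent reference implementation of the same definition
to ≈1e-16; the shipped test suite re-checks this against a separately
coded oracle.

CPM and RPKM use effective library sizes (raw size × TMM factor):
CPM = count·1e6/effective size, RPKM = CPM·1e3/length_bp.  A gene is
expressed at a time point when its mean RPKM over that time point's
replicates is ≥ 0.3; the mean pools all replicates of a time point across
experiments (the original averaging basis is unstated; pooling is the
simplest choice and is exposed in the per-sample tables if a user wants
another).  The expression level category bins the mean RPKM over the
expressed time points: low [0.3, 1), medium [1, 10), high [10, 100),
very high [100, ∞); the pattern is the subset of time points with an
expressed call, so genes partition over the 2⁴ subsets.

MDS sample QC uses the leading-log-fold-change convention: log₂ CPM with
a library-size-scaled prior count of 2, pairwise sample distance = RMS of
the 500 largest absolute log-fold-changes, classical principal-coordinate
embedding to two dimensions (deterministic up to axis sign).

## Differential expression

Counts are modelled NB(µ, φ) with variance µ + φµ², log link and log
effective library size as offset, in a one-way layout over the four time
points.  A single dispersion φ shared by all genes is estimated by
maximizing the summed Cox–Reid adjusted profile log-likelihood: for a
candidate φ, each gene's group abundances are fitted by Fisher scoring
and the per-gene contribution is ℓ̂ − ½·log det(XᵀWX); in the one-way
layout the information matrix is diagonal across groups, so the
determinant is the product of per-group working-weight sums, and groups
with zero total count for a gene (no estimable parameter) are excluded
from that gene's adjustment.  The outer maximization is a golden-section
search on log₁₀φ ∈ [−6, 1] to a width of 1e-6; the objective is unimodal
in practice and the estimate matches a dense grid scan (tested).  With
all-singleton groups the profile likelihood carries no replicate
information and estimation refuses to run.

Each time-point pair is tested with a true likelihood-ratio test: the
full model fits separate abundances in the two groups, the reduced model
a shared abundance (the one-way layout factorizes, so other groups drop
out of the difference); LR = 2(ℓ_full − ℓ_reduced) is referred to χ²₁.
Group fits use Fisher scoring to a step tolerance of 1e-10 (max 100
iterations); non-converged genes get p = NA and are excluded from the FDR
denominator with a warning rather than silently dropped.  log₂ fold
change is oriented late-vs-early and computed from the fitted abundances
with 0.125 pseudo-fragments added per group total, so all-zero groups
give large finite values instead of ±∞ while exactly balanced groups give
exactly 0; swapping the groups negates it.

Benjamini–Hochberg FDR is applied within each contrast (the DEG sets are
reported contrast-wise; the original protocol does not state within- vs
across-contrast adjustment, and within-contrast matches how the sets are
consumed downstream).  All six pairs are tested; the Venn/trend summary
reports the four contrasts of interest (10v15, 15v19, 19v29, 10v29), with
the trend over *all* significant contrasts: increasing_only /
decreasing_only when every significant fold change shares a sign,
variable otherwise.

## Homology and duplication

The flax → Arabidopsis map is inverted to give a copy count per
Arabidopsis gene; flowering-list ids with zero flax copies are reported
as missing homologues.  Duplication enrichment of flowering genes is a
Pearson χ² (1 df) on the 2×2 {flowering, other} × {single-copy,
multi-copy} table without continuity correction — the source analysis
does not state a correction, and the genome-scale margins make Yates'
adjustment immaterial.  Copy counts cover all mapped genes, not only
expressed ones.

## Enrichment

Both enrichment tests are upper-tail hypergeometric:
p = Σᵢ₌ₖ C(K,i)·C(N−K,n−i)/C(N,n).  For GO, the universe defaults to
annotated expressed genes, and a term is tested only when at least 10
genes of the input list carry it ("mapping entries" counted on the input
list, the tested tool's documented behaviour; universe-side counting is a
parameter).  GO term ancestor propagation over the ontology graph is
deliberately not performed — terms are tested as annotated, a documented
simplification.  For TF families the universe is all expressed genes,
K = all DEGs, n = expressed family members, k = family DEGs; families
with no expressed member are skipped, and the count of flowering-gene
DEGs per family is reported alongside.  BH FDR runs within each
(contrast × direction) GO run and across families for the TF test;
enrichment is FDR < 0.05.

## Clustering and candidate discovery

Per gene, X is the 4-vector of time-point means of TMM-normalized log₂
CPM (prior count 2), standardized to Z = (X − µ)/σ with the sample
(n−1) standard deviation (population σ is a parameter; the convention is
unstated in the source and immaterial to Pearson matching, which is
scale-invariant).  Flat profiles (σ = 0) carry no shape and are excluded
with a log message.

Flowering DEGs (flowering homologues significant in ≥ 1 contrast) are
K-means clustered on their Z-profiles with Euclidean distance, 50 random
restarts (uniform random member seeding) per k over k ∈ [2, 10].  The
number of clusters is a majority vote of a fixed four-index panel —
silhouette, Calinski–Harabasz, Davies–Bouldin, and the gap statistic with
50 uniform bounding-box references (smallest k satisfying
gap(k) ≥ gap(k+1) − s(k+1), else the gap-maximizing k) — with ties going
to the smaller k.  The panel approximates an all-indices vote at a
fraction of the cost; replicating a 30-index battery is out of scope.
Final clusters are relabelled deterministically by centroid trajectory so
results do not depend on K-means' internal label order; centroids are
arithmetic means of member Z-profiles.

Candidates are drawn from uncharacterized DEGs (homologue status
unknown-function or no-homologue), excluding every gene used to build the
centroids.  Each candidate's Z-profile is correlated (Pearson) with each
cluster's average Z-profile; genes with max r > 0.99 are nominated,
sorted by r.  With 4 time points this is a strict shape match, invariant
to affine rescaling of the underlying log-CPM profile.

## Synthetic data

The generator emulates the study design the pipeline assumes: 4 time
points × 3 replicates, NB counts with common dispersion (default
φ = 0.05, a plausible biological-replicate dispersion for an inbred
crop), log-uniform library sizes (8–15 M fragments) so TMM is exercised,
and six gene classes — housekeeping (50%), increasing (8%) and
decreasing (4%) monotone log-linear trends (total |log₂FC| = 2 across the
course, up:down ≈ 2:1 like the opposing trend clusters in real SAM data),
time-point-restricted (5%), unexpressed (28%, calibrated to sit below the
RPKM ≥ 0.3 call at default settings) and candidate trackers (5%,
trend-template trajectories with 0.05-SD log₂ jitter, always annotated
uncharacterized).  Expected per-gene CPM trajectories are rescaled so a
library's expected total is its nominal size, making CPM/RPKM units
meaningful for a panel-sized "genome"; a consequence is that absolute
RPKM runs higher than in a full 40k-gene transcriptome, so level
categories skew toward high — the category *boundaries*, not the realized
mixture, are what the tests pin down.  Annotations are emitted to match:
a homologue map whose copy numbers follow a duplication-rich spectrum
(20/45/20/10/5% for 1–5 copies), trend genes always characterized (they
model known biology), trackers grouped only with each other, a flowering
list drawn from characterized homologue groups containing a trend gene
plus ten ids with no flax copy (exercising missing-homologue reporting),
eight TF families of 40 with one (MADS) planted at a high trend-member
rate, and Poisson-background GO terms with one term planted in increasing
genes.  Because flowering eligibility requires a trend gene somewhere in
the homologue group, larger groups are more often flagged — so the
duplication χ² has genuine planted signal rather than a null.

What the generator does **not** emulate: correlated biological noise
between genes, batch/experiment effects, length-dependent counting bias,
isoforms, and the tagwise dispersion variation of real data.  Passing
recovery tests therefore demonstrates correctness of the inference chain
under its own model assumptions, not performance on real libraries — in
particular, the strict r > 0.99 candidate threshold recovers only ~35% of
planted trackers at φ = 0.05 with 3 replicates, a fair picture of how
selective that cut is under count noise.

## Problem sizes and determinism

Default analyses use a 5000-gene panel; calibration checks use 2000-gene
matrices over 10 seeds (DE null/power, dispersion recovery), 50 random
200 × 6 matrices (TMM oracle agreement), exhaustive enumeration to
N ≤ 60 (hypergeometric) and 8-point instances (exact K-means optimum).
Every stochastic step (simulation, K-means restarts, gap references) is
driven by an explicit seed; a pipeline rerun with the same config and
seed reproduces all outputs byte-identically, and the manifest records
the config hash, seed and per-stage gene counts for audit.
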