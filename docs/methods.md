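# Methods

`nichetrack` re-implements, as a tested pipeline, the computational
procedures used to characterize aging of the hippocampal dentate gyrus (DG)
from single-cell and Visium-style spatial transcriptomics: gene-set module
scoring with binned controls, real-time versus pseudotime aging-signature
construction (NAS and CAS), a differentiation-score regression, an age
classifier, an inflammatory-spot spatial hierarchy, and microniche
co-occurrence statistics. All stages run on synthetic data with planted
ground truth, generated by the package itself.

## Normalization, variable genes, markers

Counts are log-normalized per cell: `ln(1 + count * 10,000 / cell_total)`
(`scale_factor` configurable). Highly variable genes are ranked by clipped
standardized variance: the expected variance at each gene's mean comes from
a lowess fit (span 0.3) of log10 variance on log10 mean over raw counts,
standardized values are clipped symmetrically at `sqrt(n_cells)` and the
variance recomputed. The span is fixed rather than tuned for
reproducibility. Markers are one-vs-rest two-sided Mann-Whitney rank-sum
tests with Benjamini-Hochberg correction per group; rows are kept at
adjusted p < 0.05 and `avg_log2fc > 0.25` with
`avg_log2fc = log2((mean expm1 in + 1) / (mean expm1 out + 1))`. The
rank-sum test stands in for a hurdle-model test; only the ranking and the
cutoffs matter downstream.

## Module scoring

The score of a gene set in a cell (or spot) is the mean log-normalized
expression of the set minus the mean over expression-matched controls.
Genes are cut into 24 equal-frequency bins by mean expression (ties broken
by gene id, making the score invariant to gene and cell order); each set
gene draws 100 controls from its own bin, excluding itself, without
replacement when the bin allows and with replacement otherwise, so small
synthetic matrices never fail. Bin and control counts follow the scoring
tool's convention and are configurable; sampling is seeded. The expected
score of a random within-bin set is zero, which the tests assert
empirically.

## Real-time trends and fuzzy c-means

Per population, genes are summarized as mean log-normalized expression per
age group (young < middle < old) and row-standardized (population-sd
convention, configurable ddof). Because standardization erases amplitude,
genes whose expression does not vary across ages beyond sampling noise
would enter the clustering as pure noise profiles; they are excluded
beforehand by a one-way ANOVA flatness filter (default alpha 0.05, off with
`flat_alpha=None`), the statistical generalization of dropping constant
rows and the analogue of the non-changing-gene filtering conventional
before soft clustering of time profiles. Profiles are clustered with fuzzy
c-means (c = 8, fuzzifier 1.25 by default, k-means++ initialization,
convergence when memberships move < 1e-6; the objective is non-increasing
by construction and asserted in tests). Clusters whose centers rise
(fall) strictly with age are "up" ("down"); a gene joins its
argmax-membership cluster's set when that membership reaches 0.5.

## Signatures

NAS (Neurogenic Aging Signature) intersects the real-time up-trend with
the quiescence-enriched pseudotime module (module 1 by default) and the
real-time down-trend with the fate-committed modules (3 and 4); whether
module 2 contributes is left off by default. CAS (Core Aging Signature)
takes the whole-DG spatial pseudobulk trend genes shared by at least 2 of
the niche populations (default population list: astrocyte, qNSC, granule
cell, endothelial, microglia); provenance records the contributing
populations per gene. CAS is monotone non-increasing in `min_shared`, a
property test.

## Trajectories

PCA centers and unit-scales genes before decomposition, with a
deterministic sign convention (largest-magnitude loading positive). The
pseudotime engine is a Hastie-Stuetzle principal curve over the first 7
PCs: initialized on PC1, it alternates projecting points onto the current
200-point polyline and smoothing each coordinate against arc length with a
six-basis cubic regression spline; iterations are accepted only while the
mean squared projection distance decreases, and fitting stops when the
improvement falls below 1e-4 or after 50 iterations. Pseudotime is the
min-max-scaled arc position, oriented so a declared root group (qNSC, or
the inflammatory spots for the pseudo-spatial axis) sits low; flips are
logged. All trajectories are single-branch, matching the uni-directional
lineage the analyses address. Gene modules along pseudotime fit the same
spline per gene on a 100-point grid, z-score the profile, cluster with
seeded k-means (10 restarts), and renumber modules by mean peak position;
constant genes are reported unassigned. The default module count is 4.

## Predictors

The differentiation model trains a random forest (500 trees, seeded,
`max_features = 1/3` — the classic regression-forest mtry) on the top 50
markers per lineage class to predict principal-curve pseudotime oriented
qNSC-low, keeps the 100 most impurity-important features, and refits.
Predictions depend only on the feature genes. Because baseline gene rates
are dataset-level properties, held-out evaluation splits cells within one
dataset rather than across independently simulated ones, matching how the
original procedure trains and queries within a single atlas.

The age classifier selects highly variable genes, draws a class-balanced
training set (70% of the least populated age class, the same count from
each other class, seeded), and fits a multinomial elastic-net logistic
regression with standardized inputs via warm-started regularization paths:
mixing in {0.1, 0.5, 0.9} by 20 log-spaced inverse penalties in
[1e-3, 1e3], chosen by 10-fold cross-validated accuracy; the refit model
is scored on the held-out remainder.

## Spatial hierarchy and pseudo-space

Spots scoring strictly above 0 on the IFN-gamma-response module are
inflammatory spots (IS). Adjacency is defined on Visium array coordinates
— neighbors of (r, c) are (r, c±2) and (r±1, c±1) — with a pixel-distance
fallback (≤1.2× minimum spacing) for irregular grids. Breadth-first ring
expansion inside the region mask labels ring 1 NNS and rings 2-3 ENS1 and
ENS2; everything else is "other", and the classes partition the masked
spots. The hierarchy is computed per grid (per section). The pseudo-spatial
axis is the principal curve over spot PCs on the masked spots, oriented so
IS sits low, with gene modules numbered inside-out.

## Microniches

Circles of radius 55 um are tiled along a reference polyline (the SGZ line)
with spacing `2r(1 − overlap)`; the default 50% overlap is read linearly
along the line (spacing = r), with the 50%-shared-area alternative
available by configuration, and "55 um" is taken as a radius. The circle
run is centered along the arc so tiling is reversal-symmetric. Cells are
counted in every circle containing them (closed disc). The co-occurrence
test compares `|nBoth − nA·nB/n|` against a permutation null that shuffles
the B labels across cells (positions and A labels fixed) and recomputes
the per-circle presences and the centering term on each permuted labeling.
Shuffling presence indicators at the circle level instead is
anti-conservative here: overlapping circles, uneven occupancy and
dual-labeled cells couple the per-circle A- and B-presences even when the
labels themselves are independent, and the bias grows with the number of
circles. The odds ratio uses the Haldane +0.5 correction; saturated or
empty margins return a degenerate flag with p = 1. The proximity analysis
reports the fraction of center-labeled cells with a target cell within the
radius, excluding a dual-labeled cell as its own target.

## Synthetic data

`simulate_lineage_atlas` draws negative-binomial counts with per-cell
log-normal library sizes (median 5,000 UMIs, theta = 10 per block — block-
level rather than per-gene dispersion keeps the parameterization small).
Cells carry a latent differentiation coordinate (qNSC ~ 0.15,
aNSPC ~ 0.50, NB/IMN ~ 0.85, sd 0.07); lineage modules are logistic
windows of this coordinate (products of rising and falling logistics with
midpoints 0.30/0.55/0.80), giving interior profile peaks so peak-ordered
module numbering is well defined. Type markers add 1.5 natural-log units;
aging programs shift 0.5 log units per age step, and the up/down blocks
are jointly rebalanced per age so the aging program redistributes rather
than inflates the per-cell total — otherwise library-size normalization
leaks a spurious decreasing trend into every unregulated gene
(`balance_aging=False` disables this, used for the separable-classifier
scenario). The qNSC latent mean drifts down 0.05 per age step, planting
the deeper-quiescence-with-age effect the query stage should recover.
Defaults give 100 cells per (type, age), i.e. 300 cells per age.

`simulate_spot_grid` builds a 20x20 hexagonal lattice at 100 um pitch with
six hotspot foci in a band (tissue shows an arc of inflammatory foci along
the marginal zone rather than a single focus); the 60-gene inflammatory
block's rate is multiplied by `1 + 2·exp(−d/250 um)`. Spots are ~10-cell
pseudobulk, so dispersion is low (theta = 50) and depth high (20,000
UMIs). The decay default keeps the gradient structured through both
extended rings; the planted-hotspot recovery test uses its own pinned
scenario (one-pitch decay, denser focus band). `simulate_tissue_cells`
places uniform points with independent, exclusion-thinned, or attraction-
boosted binary labels.

What the generators do not emulate: doublets, ambient RNA, batch effects,
cell-type deconvolution within spots, spatially varying cell density, or
realistic gene-gene correlation beyond the block structure. Passing tests
therefore demonstrate that the procedures recover the structures they
target under clean planted conditions, not that they are robust to every
artifact of real data.

## Problem sizes and numerical choices

Tests and the acceptance script run the atlas at 900 cells x 800 genes
(3 ages x 300 cells), the classifier scenarios at 450 cells x
420 genes, the spot grid at 400 spots x 300 genes, and the microniche
calibration at 359 circles over 4,000-cell windows with 500 independent
replicates — sizes chosen so every planted effect is comfortably above
sampling noise while a full run stays in minutes. Convergence tolerances:
fuzzy c-means 1e-6 on memberships, principal curve 1e-4 on mean squared
projection distance, elastic-net paths 1e-2 with 2,000 iteration cap.
Ties in HVG and module-score ranking break by gene id; equal-frequency
bins use `array_split` semantics. All randomness flows from explicit
seeds; two runs with equal seeds and inputs are bit-identical.

## Known limitations

The rank-sum marker test ignores zero inflation; the single-branch
principal curve cannot represent branching trajectories; CAS/NAS gene
counts are properties of a real dataset and are not reproduced (only the
construction rules and their planted-truth behavior are); region
annotation is free-form strings, with no image handling; the fuzzifier
default 1.25 is a fixed convention rather than an estimate from the data.
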