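# Methods

This note documents the models, defaults and design choices behind
`nichemap`, and what the synthetic validation does and does not demonstrate
about real tissue data.

## Data model

A dataset is a pair of tables. The **cell table** has one row per segmented
cell: a unique `cell_id`, the `image_id` of its core, centroid coordinates
in μm (image convention: origin top-left, y downward), one non-negative
intensity column per marker, and optionally a `phenotype` label. The
**region metadata** maps each core to a patient, a region class
(`nontumor`, `invasive_margin`, `tumor`), a replicate index and a core area
in mm². When no area is given, the nominal area of a 1 mm diameter disc
(π/4 ≈ 0.785398 mm²) is used; a measured (mask-derived) area can be
supplied per core instead. All distances are Euclidean between centroids —
segmentation boundaries are not available downstream of quantification.
Missing numeric values are a hard error, never a silent NaN.

## Tissue simulator

The simulator is a marked point process on a disc of diameter 1000 μm
(configurable). Per core:

1. **Background cells.** Each phenotype is a homogeneous Poisson process at
   a configurable intensity (cells/mm²), uniform on the disc.
2. **Vessels.** A Poisson number of vessels per core (default rate 3),
   each a uniform random chord (random direction, uniform perpendicular
   offset). Endothelial cells are a Poisson process along each chord
   (default 25 expected cells for a full-diameter chord, scaled by chord
   length, with 2 μm transverse jitter).
3. **Perivascular macrophages (PVMs).** Per vessel, a Poisson number
   (default rate 3 per full-diameter vessel) of PVMs, each placed at a
   randomly chosen endothelial anchor plus an isotropic Gaussian
   displacement (default sd 8 μm, so essentially all PVMs fall within
   20 μm of endothelium).
4. **Immune aggregates.** A Poisson number of aggregates per core (default
   rate 2), each a Gaussian cloud (default sd 12 μm) of a Poisson number
   (mean 6) of cells of a single aggregate-member phenotype, centred on a
   randomly chosen PVM. The tumor region's aggregate rate is multiplied by
   the **enrichment multiplier** (default 2.0) — this is the planted
   region effect the inferential layer is asked to recover.
5. **Markers.** Intensity = phenotype prototype mean (default: 8.0 on
   characteristic markers, 0.5 elsewhere, 39-channel panel) + independent
   Gaussian noise (default sd 1.0), truncated at zero. Prototypes are
   deliberately well-spaced: the clustering stage is only asked to separate
   well-spaced populations.

Cells displaced beyond the disc are resampled (rejection at the boundary),
so every cell lies inside its core. Each core draws from an RNG stream
derived from `(seed, image_id)`, making cohorts reproducible independent of
generation order, and byte-identical across reruns of the same config.

**Background intensities are region-independent by default.** This encodes
the scientific situation the pipeline targets: cell *densities* largely
consistent across regions while *neighborhood structure* (the perivascular
niche) carries the regional signal. Densities of aggregate-member
phenotypes still rise mildly in the tumor region as a side effect of more
aggregates; this mirrors the real confound that interaction differences can
partly reflect density differences, and the defaults keep it mild by giving
member phenotypes substantial region-independent background populations.

`simulate_null_cohort` applies the first region's generative law to every
region and forces the enrichment multiplier to 1, producing cohorts in
which region labels are exchangeable within patients — the calibration
null for every permutation test in the package.

**Where the planted signal lands.** Writing N[i,j] for the directed
neighborhood statistic, doubling the tumor aggregate rate exactly doubles
the expected (PVM → member) count N[pvm, member] (pair counts scale, the
PVM count does not), while N[member, pvm] rises sublinearly through the
niche fraction among member cells (background members dilute it). The
ground-truth object therefore designates *both* directed features of each
planted member–PVM pair as carriers of the enrichment; recovery analyses
treat finding either direction as finding the planted interaction.

**What the simulator does not emulate:** segmentation errors (merged
touching cells — handled downstream by profile-based cluster merging, not
simulated), marker spillover/compensation, lognormal intensity tails,
vessel curvature and branching, spatial inhomogeneity of the background
(e.g. portal tracts), and inter-core coordinate registration. Passing the
synthetic recovery suite therefore demonstrates correctness of the
statistics and power against the modelled effect, not robustness to
segmentation artefacts or staining batch effects.

## Phenotyping

`knn_density_cluster` is a density-ascent clustering in marker space:
density = inverse mean distance to the k nearest neighbours; each cell
links to the highest-density cell among its k neighbours (ties broken
toward the smallest `cell_id`, giving determinism and row-permutation
equivariance); cells that are their own density maximum seed basins.
Because a finite-k density estimate is noisy, a single population can
fragment into several basins; basins joined by any kNN edge are therefore
consolidated into one cluster. Well-spaced populations share no kNN edges
and remain distinct, while touching populations may merge — a deliberate
bias toward under- rather than over-clustering, appropriate for panels with
well-separated prototypes. A brute-force O(n²) implementation of the same
two-stage rule serves as the test oracle.

Gating is an ordered, first-match-wins list of conjunctions of strict `>` /
`<=` marker thresholds, with unmatched cells labelled `ungated`. Intensities
are used raw for gating (an `arcsinh` helper is provided but not applied by
default).

Cluster QC implements two rules. **Rare-cluster removal**: a cluster is
dropped iff it has fewer than 5 cells in *strictly more than* one-third of
the images; zero-cell images count in the denominator and as low-count
images. **Similarity merging**: per-marker z-scored median profiles are
compared by cosine similarity and clusters at or above the threshold
(default 0.95) merge by single linkage (connected components). A profile
identical to the column mean z-scores to the zero vector; two zero vectors
count as similarity 1 so that identical profiles always merge. The merge
threshold is exposed because no principled universal value exists; 0.95
merges near-duplicates while keeping biologically distinct profiles apart
in the synthetic panels.

## Spatial features and pooling

Per image and cluster pair the package computes the abundance, directed
mean nearest-neighbour distance and neighborhood-interaction statistics
defined in the README. The neighborhood radius default of 20 μm is roughly
one cell diameter — "touching or nearly touching". Cells at exactly the
radius count as neighbours; the index cell never counts itself. Directed
pairs including i = j are retained, giving 3K + 2K² features per region.

Replicate cores are pooled per patient × region. The default `pool_cells`
policy aggregates sufficient statistics cell-weighted: summed counts over
summed areas for densities, summed pair counts over summed index-cell
counts for interactions, summed nearest-neighbour distances over summed
contributing cells for distances. Each cell's neighbours are found within
its own core — cores are disjoint coordinate frames, so cross-core pairs
are undefined by construction. The alternative `mean_of_cores` averages
per-core statistics, ignoring cores where a statistic is undefined.
`pool_cells` is the default because it stabilises statistics for rare
clusters.

Undefined features (a cluster absent from a sample) remain NaN in the
feature matrix and are imputed only at the multivariate boundary: pair
distances at the core diameter (1000 μm, a ceiling meaning "not
co-occurring"), interactions and abundances at 0. Log2 fold changes use a
pseudo-count (default 1 in the feature's units) to stay finite at zeros.

## Inference

Columns are z-scored before any multivariate analysis because the features
mix units (counts, cells/mm², %, μm); zero-variance columns are dropped
with a warning.

**PERMANOVA** uses squared Euclidean distances and the classical
sums-of-squares decomposition (pseudo-F = (SS_between/(g−1)) /
(SS_within/(n−g))). Because every patient contributes each region, the
permutation null shuffles region labels *within* patient strata by default
(unrestricted permutation is available); strata carrying a single label
contribute no permutation variation and trigger a warning. P-values use
(1 + #{F_perm ≥ F_obs}) / (1 + B), so p ≥ 1/(B+1). If every pairwise
distance is zero the statistic is defined as 0 with p = 1. Pairwise region
contrasts are separate two-group PERMANOVAs with Holm step-down adjustment.
Holm is applied only across the pairwise contrasts, not across features.

**PCA contributions** are 100 × squared loading entries of the unit-norm
principal axes; the equal-contribution reference is 100/p.

**Sparse PLS-DA** one-hot encodes and centres the class labels and, per
component, finds the leading singular pair of X′Y by power iteration,
soft-thresholding the X-weight at the (keepX+1)-th largest magnitude each
step (so at most keepX nonzero entries, renormalised to unit norm), then
deflates X and Y by regression on the component score. Initialisation is
the exact SVD of X′Y and the iteration tolerance is 1e-12, so fits are
deterministic. With keepX = p the procedure reduces exactly to dense
NIPALS PLS2 — verified against an independent implementation to 1e-8.
keepX defaults to 25 per component: small enough to be interpretable,
large enough to capture a multi-feature niche signature.

**Paired permutation tests** use the paired t statistic on per-patient
differences with a sign-flip null, enumerated exactly whenever 2ⁿ ≤ the
permutation budget (n ≤ 13 at the default 9999); otherwise Monte Carlo with
the (1+more extreme)/(1+B) convention. All-zero differences give p = 1.
These tests replace the classical Friedman/Dunn, Wilcoxon and two-way
ANOVA/LSD comparisons: one permutation machine, assumption-free for the
paired design, used everywhere a single feature or band is contrasted.

## Proximity bands

Each query cell is assigned to exactly one half-open band [lo, hi) of
distance to its *nearest* reference cell (bands of 20 μm to 100 μm by
default, plus a beyond-max bin), so per-image band counts sum to the query
count. A query cell belonging to the reference population is excluded from
its own reference set. The control analysis swaps the reference for an
arbitrary phenotype set (e.g. all non-endothelial cells). Band contrasts
are paired sign-flip permutation tests on per-image counts. Under complete
spatial randomness band occupancy around an isolated reference cell is
proportional to annulus area (400π : 1200π : 2000π : 2800π : 3600π), which
the tests verify by Monte Carlo.

## Problem sizes in the validation suite

Monte-Carlo calibrations run on scaled-down cohorts (8 patients, 5
phenotypes, one core per region, 199–999 permutations, 200 replicates);
niche-recovery runs use the full default design (16 patients × 3 regions ×
3 cores, 11 phenotypes, 20 seeds). These sizes give binomial error bars
tight enough to detect miscalibration (95% band ≈ [0.02, 0.09] around 0.05
at 200 replicates) while keeping the whole suite fast on a single core.
The niche-recovery analysis follows the immune-focused procedure: clusters
are first restricted to CD45⁺ profiles (cluster-median CD45 above
threshold) before the neighborhood sPLS-DA, which removes parenchymal,
stromal and endothelial features from the discriminant ranking.

## Known limitations

* No boundary-effect correction for the spatial statistics: cores are
  equal-sized discs, so edge effects are comparable across regions and
  largely cancel in contrasts, but absolute interaction values are biased
  low near the rim.
* The directed mean nearest-neighbour distance is one of several possible
  readings of "average distance between clusters"; it was chosen because
  it is bounded, neighborhood-relevant and standard in spatial cytometry.
  The mean over all pairs is not implemented.
* The density-ascent clustering consolidates kNN-connected basins and will
  merge genuinely overlapping populations; it is intended for well-spaced
  phenotype prototypes, not for resolving continua.
* PERMANOVA is single-factor with patient strata; multi-factor designs and
  interaction terms are out of scope.
* Proximity uses the nearest reference *cell*, not the nearest vessel
  object; distances to vessel lumina would require masks the pipeline does
  not ingest.
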