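# nichemap

Spatial neighborhood analysis for segmented multiplexed-imaging data
(imaging mass cytometry and similar), built around the question of how
immune-cell neighborhoods differ between tumor, invasive-margin and adjacent
nontumor tissue regions — and in particular whether perivascular macrophages
(PVMs) and the immune aggregates around them are enriched near tumor
endothelium.

It is aimed at computational biologists who already have **segmented
single-cell tables** (one row per cell: image/core ID, centroid in μm,
marker intensities) from a tissue-microarray design — e.g. several patients,
each contributing replicate 1 mm cores from multiple tissue regions — and
who want a tested, reproducible implementation of the analysis stack rather
than an image-processing tool.

## What it computes

For each image with phenotype-labelled cells (labels from KNN-density
clustering, threshold gating, or supplied directly), with clusters indexed
*i, j = 1..K*:

* **Abundance** per cluster: count, density (cells/mm²), percentage of total
  cells.
* **Directed mean nearest-neighbor distances**
  *D[i,j]* = mean over cluster-*i* cells of the distance to the nearest
  cluster-*j* cell (nearest *other* cell for *i = j*).
* **Neighborhood interactions**
  *N[i,j]* = mean over cluster-*i* cells of the number of cluster-*j* cells
  within radius *r* (default 20 μm), excluding the index cell. The exact
  pair-count identity *nᵢ·N[i,j] = nⱼ·N[j,i]* is preserved and used as an
  internal check.

Per-image summaries are pooled into one row per patient × region (3K + 2K²
named features per region; with K = 47 clusters and 3 regions that is
13,677 feature slots per patient), then analysed with:

* **PERMANOVA** on Euclidean distances over z-scored features, with
  permutations stratified by patient (the design is paired) and
  Holm-corrected pairwise region contrasts;
* **PCA contribution ranking** with the equal-contribution reference line
  100/p;
* **sparse PLS-DA** (one-hot response, per-component soft-thresholded
  loadings with at most `keepX` nonzero entries) for discriminative feature
  selection;
* **paired permutation t-tests** (sign-flip null, exact enumeration when
  2ⁿ fits the permutation budget) on single features;
* **proximity-band analysis**: counts of query cells (e.g. VEGFA⁺
  macrophages) per 20 μm band of distance to the nearest reference cell
  (e.g. CD34⁺ endothelium) over 0–100 μm, with a non-reference control and
  paired band contrasts.

A marked point-process **tissue simulator** generates cohorts of 1 mm disc
cores with known ground truth — Poisson background phenotypes, vessels as
random chords carrying Poisson endothelium, PVMs Gaussian-displaced from
endothelial anchors, immune aggregates clustered on PVMs, and a configurable
tumor-region enrichment of the aggregate–PVM interaction — so every stage
can be validated against a recoverable signal and a calibratable null.

## Worked example

```python
from nichemap.pipeline import run_pipeline

report = run_pipeline(
    {
        "sim": {"n_patients": 8, "replicates_per_region": 3},
        "stats": {"n_permutations": 999},
        "seed": 7,
    },
    "out",
)
```

or equivalently `nichemap run --config run.yaml --out out --seed 7`. This
simulates a cohort of 8 patients × 3 regions × 3 cores (42,281 cells across
72 images), assembles a 24 × 275 feature matrix and prints/writes:

```
permanova: F=1.078 R2=0.093 p=0.2580
  nontumor vs tumor: p=0.0810 holm=0.2430
flagged designated pairs: ['neigh_trm_cd4_pvm']
bands profile: {'0-20': 516, '20-40': 12, '40-60': 0, '60-80': 0, '80-100': 0}
band 0-20 vs 40-60 p: 0.001
```

Reading: at this cohort size the global PERMANOVA over all 275 spatial
features does not reach significance (the planted effect touches only the
niche features), but the pipeline still flags the planted aggregate→PVM
neighborhood interaction (`neigh_trm_cd4_pvm`: selected by sPLS-DA component
1 *and* paired-test p ≤ 0.05 between tumor and nontumor), and the PVM
proximity profile peaks sharply in the 0–20 μm band from endothelium
(516 of 528 PVMs; paired band contrast p = 0.001).

Artifacts written to `out/`: `cells.csv`, `metadata.csv`,
`ground_truth.csv`, `feature_matrix.csv`, `loadings.csv`, `bands.csv` and
the machine-readable `stats_report.json` (byte-identical across reruns with
the same config and seed).

## Command-line interface

`nichemap` exposes the stages individually:

```
nichemap simulate --config sim.yaml --out DIR --seed N [--null]
nichemap cluster  --cells cells.csv --k 30 --out clusters.csv
nichemap gate     --cells cells.csv --gates gates.yaml --out labelled.csv
nichemap qc       --cells labelled.csv --meta metadata.csv --out qc.csv
nichemap features --cells labelled.csv --meta metadata.csv --radius 20 \
                  --pooling pool_cells --out feature_matrix.csv
nichemap permanova --features feature_matrix.csv --permutations 9999 --seed 0
nichemap splsda    --features feature_matrix.csv --keepx 25 --out loadings.csv
nichemap paired-test --features feature_matrix.csv --feature neigh_a_b
nichemap bands    --cells labelled.csv --reference endothelial_cd34 \
                  --query pvm --width 20 --max 100 --out bands.csv
nichemap run      --config run.yaml --out DIR --seed N
```

## Layout

```
src/nichemap/
  io_tables.py    cell/metadata/feature CSV I/O and dataset validation
  simulate.py     marked point-process cohort simulator + ground truth
  phenotyping.py  KNN-density clustering, gating, cluster QC (filter/merge)
  spatial.py      per-image spatial statistics and feature assembly
  stats.py        PERMANOVA, PCA contributions, sparse PLS-DA, paired tests
  proximity.py    distance-band proximity analysis
  pipeline.py     end-to-end orchestration from a YAML config
  cli.py          click-based command-line interface
docs/methods.md   modelling assumptions, parameter choices, limitations
```
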