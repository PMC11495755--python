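"""Per-image spatial statistics and cohort feature assembly.

For each image the pipeline computes, per phenotype cluster:

* **abundance** — count, density (cells/mm^2) and percentage of total cells;
* **directed mean nearest-neighbour distances** D[i, j]: the mean, over cells
  of cluster i, of the distance to the nearest cluster-j cell (for i == j,
  the nearest *other* cell of the same cluster);
* **neighborhood interactions** N[i, j]: the mean, over cells of cluster i,
  of the number of cluster-j cells within a fixed radius (default 20 um),
  excluding the index cell itself for i == j.

All distances are Euclidean on centroids.  N satisfies the exact pair-count
identity n_i * N[i, j] = n_j * N[j, i], which doubles as an implementation
check.  Per-image summaries are assembled into one row per patient x region
sample, either by pooling replicate cores' cells (cell-weighted, summed
areas; each cell's neighbours are taken within its own core) or by averaging
per-core statistics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AssemblyError, ContractError, ParameterError
from .io_tables import CellTable, RegionMetadata

POOLING_POLICIES = ("pool_cells", "mean_of_cores")


@dataclass
class NeighborhoodMatrix:
    """K x K directed neighborhood-interaction matrix for one image."""

    clusters: list
    matrix: np.ndarray       # N[i, j]; NaN rows where n_i == 0
    counts: np.ndarray       # n_i per cluster
    pair_counts: np.ndarray  # total directed neighbour count = n_i * N[i, j]
    radius: float


@dataclass
class DistanceSummary:
    """K x K directed mean nearest-neighbour distance matrix for one image."""

    clusters: list
    matrix: np.ndarray  # D[i, j]; NaN where undefined


@dataclass
class AbundanceSummary:
    """Per-cluster count, density and percentage for one image."""

    clusters: list
    counts: np.ndarray
    density: np.ndarray     # cells/mm^2
    percentage: np.ndarray  # NaN when the image is empty
    area_mm2: float


def _coords_and_labels(df: pd.DataFrame, clusters):
    if "phenotype" not in df.columns or df["phenotype"].isna().any():
        raise ContractError("all cells must carry a phenotype label")
    labels = df["phenotype"].to_numpy(dtype=object)
    if clusters is None:
        clusters = sorted(set(labels))
    index = {c: k for k, c in enumerate(clusters)}
    unknown = set(labels) - set(index)
    if unknown:
        raise ContractError(f"cells labelled outside the cluster set: {sorted(unknown)}")
    codes = np.array([index[v] for v in labels], dtype=np.int64)
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    return xy, codes, list(clusters)


def neighborhood_matrix(
    cells: pd.DataFrame, radius: float = 20.0, clusters=None
) -> NeighborhoodMatrix:
    """Directed neighborhood interactions for one image's labelled cells.

    ``cells`` is a per-image slice of a cell table (``CellTable.for_image``).
    Cells at distance exactly ``radius`` count as neighbours; the index cell
    never counts as its own neighbour.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    xy, codes, clusters = _coords_and_labels(cells, clusters)
    K = len(clusters)
    counts = np.bincount(codes, minlength=K).astype(np.int64)
    pair = np.zeros((K, K), dtype=np.int64)
    if len(xy) > 1:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs):
            a = codes[pairs[:, 0]]
            b = codes[pairs[:, 1]]
            np.add.at(pair, (a, b), 1)
            np.add.at(pair, (b, a), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        N = pair / counts[:, None].astype(float)
    N[counts == 0, :] = np.nan
    return NeighborhoodMatrix(
        clusters=clusters, matrix=N, counts=counts, pair_counts=pair, radius=radius
    )


def distance_summary(cells: pd.DataFrame, clusters=None) -> DistanceSummary:
    """Directed mean nearest-neighbour distances for one image.

    D[i, j] is undefined (NaN) when cluster i is absent, cluster j is absent,
    or i == j with fewer than two cells.
    """
    xy, codes, clusters = _coords_and_labels(cells, clusters)
    K = len(clusters)
    sums, contrib = _nn_distance_sums(xy, codes, K)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = sums / contrib
    D[contrib == 0] = np.nan
    return DistanceSummary(clusters=clusters, matrix=D)


def _nn_distance_sums(xy, codes, K):
    """Sum of nearest-j distances over i-cells, and contributing cell counts."""
    sums = np.zeros((K, K))
    contrib = np.zeros((K, K), dtype=np.int64)
    by_cluster = [np.flatnonzero(codes == k) for k in range(K)]
    trees = [cKDTree(xy[idx]) if len(idx) else None for idx in by_cluster]
    for i in range(K):
        src = by_cluster[i]
        if not len(src):
            continue
        for j in range(K):
            tree = trees[j]
            if tree is None:
                continue
            if i == j:
                if len(src) < 2:
                    continue
                d, _ = tree.query(xy[src], k=2)
                d = d[:, 1]
            else:
                d, _ = tree.query(xy[src], k=1)
            sums[i, j] = float(np.sum(d))
            contrib[i, j] = len(src)
    return sums, contrib


def cluster_abundance(
    cells: pd.DataFrame, area_mm2: float, clusters=None
) -> AbundanceSummary:
    """Count, density and percentage per cluster for one image.

    Clusters named in ``clusters`` but absent from the image get count 0 and
    density 0; percentages are NaN for an empty image.
    """
    if area_mm2 <= 0:
        raise ParameterError("area_mm2 must be positive")
    if len(cells):
        _, codes, clusters = _coords_and_labels(cells, clusters)
    else:
        clusters = list(clusters) if clusters is not None else []
        codes = np.empty(0, dtype=np.int64)
    K = len(clusters)
    counts = np.bincount(codes, minlength=K).astype(np.int64)
    total = counts.sum()
    density = counts / area_mm2
    pct = 100.0 * counts / total if total > 0 else np.full(K, np.nan)
    return AbundanceSummary(
        clusters=clusters, counts=counts, density=density,
        percentage=pct, area_mm2=area_mm2,
    )


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Samples (patient x region) by named spatial features.

    Columns: ``count_c`` / ``density_c`` / ``pct_c`` per cluster, then
    ``dist_ci_cj`` and ``neigh_ci_cj`` for every ordered cluster pair
    (including i == j), giving ``3K + 2K^2`` columns.  Missing values (absent
    clusters) stay NaN here; imputation happens only at the multivariate-
    analysis boundary.
    """

    data: pd.DataFrame  # MultiIndex (patient_id, region_class)
    clusters: list
    provenance: dict = field(default_factory=dict)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_feature_slots_per_patient(self) -> int:
        K = len(self.clusters)
        n_regions = self.data.index.get_level_values("region_class").nunique()
        return n_regions * (3 * K + 2 * K * K)

    def region_labels(self) -> pd.Series:
        return self.data.index.get_level_values("region_class").to_series(
            index=self.data.index
        )

    def patient_labels(self) -> pd.Series:
        return self.data.index.get_level_values("patient_id").to_series(
            index=self.data.index
        )


def feature_columns(clusters) -> list[str]:
    cols = [f"count_{c}" for c in clusters]
    cols += [f"density_{c}" for c in clusters]
    cols += [f"pct_{c}" for c in clusters]
    cols += [f"dist_{a}_{b}" for a in clusters for b in clusters]
    cols += [f"neigh_{a}_{b}" for a in clusters for b in clusters]
    return cols


@dataclass
class _ImageSummary:
    counts: np.ndarray
    area_mm2: float
    pair_counts: np.ndarray
    nn_sums: np.ndarray
    nn_contrib: np.ndarray


def summarize_image(
    cells: pd.DataFrame, area_mm2: float, radius: float, clusters
) -> _ImageSummary:
    """All sufficient statistics of one image for either pooling policy."""
    K = len(clusters)
    if len(cells):
        xy, codes, _ = _coords_and_labels(cells, clusters)
    else:
        xy = np.empty((0, 2))
        codes = np.empty(0, dtype=np.int64)
    counts = np.bincount(codes, minlength=K).astype(np.int64)
    pair = np.zeros((K, K), dtype=np.int64)
    if len(xy) > 1:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs):
            a, b = codes[pairs[:, 0]], codes[pairs[:, 1]]
            np.add.at(pair, (a, b), 1)
            np.add.at(pair, (b, a), 1)
    sums, contrib = _nn_distance_sums(xy, codes, K)
    return _ImageSummary(counts, float(area_mm2), pair, sums, contrib)


def assemble_features(
    cells: CellTable,
    meta: RegionMetadata,
    radius: float = 20.0,
    pooling: str = "pool_cells",
    clusters=None,
) -> FeatureMatrix:
    """Build the patient x region feature matrix from a labelled cell table.

    ``pool_cells`` (default) recomputes every statistic on the union of the
    replicate cores' cells with summed areas (cell-weighted; each cell's
    neighbours live in its own core's coordinate frame).  ``mean_of_cores``
    averages per-core statistics, ignoring cores where a statistic is
    undefined.
    """
    if pooling not in POOLING_POLICIES:
        raise ParameterError(f"pooling must be one of {POOLING_POLICIES}")
    if not cells.has_phenotype:
        raise ContractError("cells must be labelled before feature assembly")
    if clusters is None:
        clusters = sorted(set(cells.data["phenotype"]))
    K = len(clusters)

    summaries: dict[str, _ImageSummary] = {}
    for _, row in meta.data.iterrows():
        img = row["image_id"]
        summaries[img] = summarize_image(
            cells.for_image(img), row["area_mm2"], radius, clusters
        )

    cols = feature_columns(clusters)
    samples = []
    index = []
    groups = meta.data.groupby(["patient_id", "region_class"], sort=True)
    for (patient, region), g in groups:
        imgs = list(g["image_id"])
        if not imgs:  # pragma: no cover - groupby never yields empty groups
            raise AssemblyError(f"no images for {patient} {region}")
        ss = [summaries[i] for i in imgs]
        if pooling == "pool_cells":
            counts = np.sum([s.counts for s in ss], axis=0)
            area = float(np.sum([s.area_mm2 for s in ss]))
            total = counts.sum()
            density = counts / area
            pct = 100.0 * counts / total if total > 0 else np.full(K, np.nan)
            pair = np.sum([s.pair_counts for s in ss], axis=0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                neigh = pair / counts[:, None].astype(float)
            neigh[counts == 0, :] = np.nan
            nn_sums = np.sum([s.nn_sums for s in ss], axis=0)
            nn_contrib = np.sum([s.nn_contrib for s in ss], axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = nn_sums / nn_contrib
            dist[nn_contrib == 0] = np.nan
        else:  # mean_of_cores
            counts = np.mean([s.counts for s in ss], axis=0)
            density = np.mean([s.counts / s.area_mm2 for s in ss], axis=0)
            pcts = []
            for s in ss:
                t = s.counts.sum()
                pcts.append(100.0 * s.counts / t if t > 0 else np.full(K, np.nan))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pct = np.nanmean(pcts, axis=0)
                neighs, dists = [], []
                for s in ss:
                    with np.errstate(invalid="ignore", divide="ignore"):
                        nmat = s.pair_counts / s.counts[:, None].astype(float)
                    nmat[s.counts == 0, :] = np.nan
                    neighs.append(nmat)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        dmat = s.nn_sums / s.nn_contrib
                    dmat[s.nn_contrib == 0] = np.nan
                    dists.append(dmat)
                neigh = np.nanmean(neighs, axis=0)
                dist = np.nanmean(dists, axis=0)
        row_vals = np.concatenate(
            [counts, density, pct, dist.ravel(), neigh.ravel()]
        )
        samples.append(row_vals)
        index.append((patient, region))

    idx = pd.MultiIndex.from_tuples(index, names=["patient_id", "region_class"])
    df = pd.DataFrame(samples, index=idx, columns=cols)
    return FeatureMatrix(
        data=df,
        clusters=list(clusters),
        provenance={"radius_um": radius, "pooling": pooling, "K": K},
    )


def log2_fold_change(
    fm: FeatureMatrix,
    feature: str,
    region_a: str = "tumor",
    region_b: str = "nontumor",
    pseudo: float = 1.0,
) -> pd.Series:
    """Per-patient log2((x_a + pseudo) / (x_b + pseudo)) for one feature.

    The pseudo-count (default 1, in the feature's own units) keeps the ratio
    finite when a cluster is absent from one region.
    """
    col = fm.data[feature].unstack("region_class")
    if region_a not in col.columns or region_b not in col.columns:
        raise ParameterError(f"regions {region_a!r}/{region_b!r} not both present")
    a = col[region_a]
    b = col[region_b]
    return np.log2((a + pseudo) / (b + pseudo)).rename(f"lfc_{feature}")
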