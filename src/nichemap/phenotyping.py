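"""Phenotype assignment and cluster quality control.

Two labelling routes are supported, mirroring common cytometry practice:

* **KNN-density clustering** (X-shift-style density ascent): per-cell density
  is the inverse mean distance to the k nearest neighbours in marker space;
  each cell links to the densest cell among its k neighbours, and cells that
  are their own local density maximum seed clusters.
* **Threshold gating**: an ordered list of named gates, each a conjunction of
  strict-``>`` / ``<=`` marker predicates; first match wins and unmatched
  cells become ``"ungated"``.

Cluster QC implements two rules applied to immune-cluster panels before
neighborhood analysis: removal of clusters with fewer than ``min_cells``
cells in strictly more than a given fraction of images, and single-linkage
merging of clusters whose z-scored median marker profiles are nearly
collinear (cosine similarity above a threshold).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .errors import GateSpecError, ParameterError
from .io_tables import CellTable


def arcsinh_transform(expr: pd.DataFrame, cofactor: float = 5.0) -> pd.DataFrame:
    """Standard cytometry variance-stabilising transform, x -> asinh(x / cofactor)."""
    if cofactor <= 0:
        raise ParameterError("cofactor must be positive")
    return np.arcsinh(expr / cofactor)


# ---------------------------------------------------------------------------
# KNN-density clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Result of density clustering: integer label per cell, labels in 0..K-1."""

    labels: np.ndarray
    K: int
    k_neighbors: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)


def _density_ascent(dens: np.ndarray, neigh_idx: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Link every cell to its best neighbour under the strict key (density, -order).

    ``order`` is the tie-break rank (smaller = preferred), typically the rank
    of the cell_id; the key ordering is a strict total order, so the linkage
    graph is a forest and ascent terminates at unique roots.
    """
    n = len(dens)

    def greater(a, b):  # key(a) > key(b), key = (density, -order)
        return dens[a] > dens[b] or (dens[a] == dens[b] and order[a] < order[b])

    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        best = -1
        for j in neigh_idx[i]:
            if greater(j, i) and (best == -1 or greater(j, best)):
                best = j
        parent[i] = best
    return parent


def _roots_and_labels(parent: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, int]:
    n = len(parent)
    root = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        path = []
        j = i
        while root[j] == -1 and parent[j] != -1:
            path.append(j)
            j = parent[j]
        r = root[j] if root[j] != -1 else j
        root[i] = r
        for p in path:
            root[p] = r
    # canonical labels: clusters numbered by ascending tie-break order of root
    uniq = np.unique(root)
    uniq = uniq[np.argsort(order[uniq], kind="stable")]
    remap = {r: k for k, r in enumerate(uniq)}
    labels = np.array([remap[r] for r in root], dtype=int)
    return labels, len(uniq)


def knn_density_cluster(
    expr: pd.DataFrame | np.ndarray,
    k_neighbors: int,
    cell_ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Density-ascent clustering on a cells x markers matrix.

    Density per cell is the inverse mean distance to its ``k_neighbors``
    nearest neighbours (Euclidean, marker space).  Each cell links to the
    highest-density cell among its neighbours; ties are broken toward the
    smallest cell_id, making the result deterministic and equivariant under
    row permutation.  Cells that are their own density maximum seed basins,
    and basins connected by a kNN edge are consolidated into one cluster, so
    a population fragmented by density-estimate noise maps to one label while
    well-spaced populations (no cross kNN edges) stay separate.
    """
    X = np.asarray(expr, dtype=float)
    n = len(X)
    if k_neighbors < 1:
        raise ParameterError("k_neighbors must be >= 1")
    if k_neighbors >= n:
        raise ParameterError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    if not np.isfinite(X).all():
        raise ParameterError("expression matrix must be finite")

    if cell_ids is not None:
        order = np.argsort(np.argsort(np.asarray(cell_ids, dtype=object), kind="stable"))
    else:
        order = np.arange(n)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop one occurrence of self per row (may not be first with duplicate points)
    self_pos = np.argmax(idx == np.arange(n)[:, None], axis=1)
    has_self = idx[np.arange(n), self_pos] == np.arange(n)
    keep = np.ones_like(idx, dtype=bool)
    keep[np.arange(n)[has_self], self_pos[has_self]] = False
    keep[~has_self, -1] = False  # self not found (duplicates): drop farthest
    neigh_idx = idx[keep].reshape(n, k_neighbors)
    neigh_dist = dist[keep].reshape(n, k_neighbors)

    mean_dist = neigh_dist.mean(axis=1)
    with np.errstate(divide="ignore"):
        dens = np.where(mean_dist > 0, 1.0 / mean_dist, np.inf)

    parent = _density_ascent(dens, neigh_idx, order)
    labels, K = _roots_and_labels(parent, order)
    labels, K = _consolidate_basins(labels, neigh_idx, order)
    return ClusterAssignment(labels=labels, K=K, k_neighbors=k_neighbors)


def _consolidate_basins(labels, neigh_idx, order):
    """Merge ascent basins whose k-neighbourhood graphs touch.

    A noisy kNN density estimate splits one well-separated population into
    several local-maximum basins; any two basins joined by a k-nearest-
    neighbour edge belong to the same connected population and are merged
    (mode consolidation).  Well-spaced populations share no kNN edges and
    stay distinct.
    """
    n = len(labels)
    root = np.arange(int(labels.max()) + 1 if n else 0)

    def find(a):
        while root[a] != a:
            root[a] = root[root[a]]
            a = root[a]
        return a

    for i in range(n):
        li = find(labels[i])
        for j in neigh_idx[i]:
            lj = find(labels[j])
            if li != lj:
                root[max(li, lj)] = min(li, lj)
                li = min(li, lj)
    merged = np.array([find(l) for l in labels])
    # canonical labels: number components by ascending tie-break order of
    # their first member
    first = {}
    for i in np.argsort(order, kind="stable"):
        first.setdefault(merged[i], len(first))
    out = np.array([first[m] for m in merged], dtype=int)
    return out, len(first)


# ---------------------------------------------------------------------------
# cluster profiles + QC
# ---------------------------------------------------------------------------

@dataclass
class ClusterProfile:
    """Per-cluster median marker profile and per-image cell counts."""

    medians: pd.DataFrame          # clusters x markers
    counts_per_image: pd.DataFrame  # clusters x images (zero columns kept)

    @property
    def clusters(self) -> list:
        return list(self.medians.index)


def build_profiles(
    cells: CellTable, images: Iterable[str] | None = None
) -> ClusterProfile:
    """Summarise labelled cells into a :class:`ClusterProfile`.

    ``images`` lists the image universe for the per-image counts; images with
    zero cells still count toward the rare-cluster rule's denominator, so pass
    the metadata's image list when images can be empty.
    """
    if not cells.has_phenotype:
        raise ParameterError("cells must carry phenotype labels")
    df = cells.data
    medians = df.groupby("phenotype")[list(cells.markers)].median()
    counts = (
        df.groupby(["phenotype", "image_id"]).size().unstack(fill_value=0)
    )
    if images is not None:
        counts = counts.reindex(columns=list(images), fill_value=0)
    counts = counts.reindex(index=medians.index, fill_value=0)
    return ClusterProfile(medians=medians, counts_per_image=counts)


def filter_rare_clusters(
    profile: ClusterProfile,
    min_cells: int = 5,
    image_fraction: float = 1.0 / 3.0,
) -> tuple[list, dict]:
    """Remove clusters with < ``min_cells`` cells in strictly more than
    ``image_fraction`` of images.

    Returns (kept cluster list, removal log mapping removed cluster -> the
    offending image fraction).  Zero-cell images count both in the
    denominator and as "< min_cells" images.
    """
    counts = profile.counts_per_image
    n_images = counts.shape[1]
    if n_images == 0:
        return list(profile.clusters), {}
    frac_low = (counts < min_cells).sum(axis=1) / n_images
    removed = frac_low > image_fraction
    kept = [c for c in profile.clusters if not removed[c]]
    log = {c: float(frac_low[c]) for c in profile.clusters if removed[c]}
    return kept, log


def _profile_cosine(medians: pd.DataFrame) -> np.ndarray:
    """Cosine similarity of per-marker z-scored median profiles.

    A profile equal to the column mean z-scores to the zero vector; two zero
    vectors count as identical (similarity 1), zero vs non-zero as 0.
    """
    z = medians.copy()
    std = z.std(axis=0, ddof=0)
    mean = z.mean(axis=0)
    z = (z - mean).div(std.where(std > 0, 1.0), axis=1)
    z.loc[:, std <= 0] = 0.0
    M = z.to_numpy()
    norms = np.linalg.norm(M, axis=1)
    K = len(M)
    sim = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if norms[i] == 0 and norms[j] == 0:
                sim[i, j] = 1.0
            elif norms[i] == 0 or norms[j] == 0:
                sim[i, j] = 0.0
            else:
                sim[i, j] = float(M[i] @ M[j] / (norms[i] * norms[j]))
    return sim


def merge_similar_clusters(
    profile: ClusterProfile, similarity_threshold: float = 0.95
) -> dict:
    """Single-linkage merge of clusters with near-identical marker profiles.

    Clusters whose z-scored median profiles have cosine similarity >=
    ``similarity_threshold`` are connected; connected components merge.
    Returns a mapping old label -> new label (the smallest member label of
    each component, in profile order).
    """
    if not (0.0 < similarity_threshold <= 1.0):
        raise ParameterError("similarity_threshold must be in (0, 1]")
    clusters = profile.clusters
    K = len(clusters)
    if K == 0:
        return {}
    sim = _profile_cosine(profile.medians)
    adj = coo_matrix(sim >= similarity_threshold)
    _, comp = connected_components(adj, directed=False)
    # representative = first cluster (in profile order) of each component
    rep: dict[int, object] = {}
    mapping = {}
    for c, lab in zip(comp, clusters):
        rep.setdefault(c, lab)
        mapping[lab] = rep[c]
    return mapping


def apply_cluster_mapping(cells: CellTable, mapping: dict) -> CellTable:
    """Relabel a cell table's phenotypes through a merge mapping."""
    labels = [mapping.get(v, v) for v in cells.data["phenotype"]]
    return cells.with_phenotype(labels)


def select_clusters_by_marker(
    profile: ClusterProfile, marker: str, cutoff: float
) -> list:
    """Clusters whose median intensity of ``marker`` exceeds ``cutoff``.

    The usual immune-focus step: restrict a neighborhood analysis to CD45+
    clusters by selecting on cluster-median CD45.
    """
    if marker not in profile.medians.columns:
        raise ParameterError(f"marker {marker!r} not in profiles")
    med = profile.medians[marker]
    return [c for c in profile.clusters if med[c] > cutoff]


def subset_to_clusters(cells: CellTable, keep) -> CellTable:
    """Drop cells whose phenotype is not in ``keep`` (e.g. non-immune clusters)."""
    if not cells.has_phenotype:
        raise ParameterError("cells must carry phenotype labels")
    mask = cells.data["phenotype"].isin(set(keep))
    return CellTable(cells.data[mask].reset_index(drop=True), cells.markers)


# ---------------------------------------------------------------------------
# threshold gating
# ---------------------------------------------------------------------------

_OPS = {">", "<="}


@dataclass
class Gate:
    """One named gate: a conjunction of marker threshold predicates."""

    name: str
    predicates: list[tuple[str, str, float]]  # (marker, op, cutoff)

    def __post_init__(self):
        for marker, op, cutoff in self.predicates:
            if op not in _OPS:
                raise GateSpecError(f"gate {self.name!r}: unknown operator {op!r}")
            if not np.isfinite(cutoff):
                raise GateSpecError(f"gate {self.name!r}: cutoff must be finite")


@dataclass
class GateSpec:
    """Ordered, first-match-wins list of gates; unmatched cells -> 'ungated'."""

    gates: list[Gate] = field(default_factory=list)
    ungated_label: str = "ungated"

    @classmethod
    def from_yaml(cls, path) -> "GateSpec":
        """Load a gate hierarchy from YAML::

            gates:
              - name: t_cell
                where: {CD45: ">4", CD3: ">4"}
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        gates = []
        for entry in doc.get("gates", []):
            preds = []
            for marker, rule in entry["where"].items():
                rule = str(rule).strip()
                if rule.startswith("<="):
                    preds.append((marker, "<=", float(rule[2:])))
                elif rule.startswith(">"):
                    preds.append((marker, ">", float(rule[1:])))
                else:
                    raise GateSpecError(f"cannot parse predicate {rule!r}")
            gates.append(Gate(entry["name"], preds))
        return cls(gates=gates, ungated_label=doc.get("ungated_label", "ungated"))


def apply_gates(cells: CellTable, spec: GateSpec) -> CellTable:
    """Label cells by the first gate whose predicates all hold (strict ``>``).

    Row order never affects the result.  Raises :class:`GateSpecError` when a
    gate references a marker absent from the table.
    """
    for gate in spec.gates:
        for marker, _, _ in gate.predicates:
            if marker not in cells.markers:
                raise GateSpecError(
                    f"gate {gate.name!r} references absent marker {marker!r}"
                )
    n = cells.n_cells
    labels = np.full(n, spec.ungated_label, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for gate in spec.gates:
        mask = np.ones(n, dtype=bool)
        for marker, op, cutoff in gate.predicates:
            vals = cells.data[marker].to_numpy(dtype=float)
            mask &= (vals > cutoff) if op == ">" else (vals <= cutoff)
        hit = mask & unassigned
        labels[hit] = gate.name
        unassigned &= ~hit
    return cells.with_phenotype(labels)
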