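"""Reading, validation and writing of the tabular formats the pipeline exchanges.

The pipeline consumes segmented single-cell tables (one row per cell with an
image/core identifier, centroid coordinates in micrometres and one column per
marker channel) plus a region-metadata table mapping each core to a patient, a
tissue region class (nontumor / invasive_margin / tumor), a replicate index and
a core area.  Everything is plain UTF-8 CSV with a header, "." decimal and no
silent NaN: a missing numeric value is an error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError, DataIntegrityError

REGION_CLASSES = ("nontumor", "invasive_margin", "tumor")

#: Area of a 1 mm diameter disc core, mm^2 (pi * 0.5^2).
DEFAULT_CORE_AREA_MM2 = math.pi * 0.25

_CELL_REQUIRED = ("cell_id", "image_id", "x_um", "y_um")
_META_REQUIRED = ("image_id", "patient_id", "region_class", "replicate")


@dataclass
class CellTable:
    """Segmented single cells: one row per cell.

    ``data`` holds columns ``cell_id``, ``image_id``, ``x_um``, ``y_um``, one
    numeric column per marker (in ``markers`` order) and optionally
    ``phenotype``.  Invariants (unique cell IDs, finite coordinates, no missing
    marker intensities) are enforced at construction.
    """

    data: pd.DataFrame
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.data
        for col in _CELL_REQUIRED:
            if col not in df.columns:
                raise DataFormatError(f"cell table is missing required column {col!r}")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise DataIntegrityError(f"duplicate cell_id {dup!r} in cell table")
        coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise DataFormatError("cell coordinates must be finite (no missing values)")
        for m in self.markers:
            if m not in df.columns:
                raise DataFormatError(f"marker column {m!r} missing from cell table")
            vals = pd.to_numeric(df[m], errors="coerce")
            if vals.isna().any():
                raise DataFormatError(f"marker column {m!r} has missing/non-numeric values")
            if (vals < 0).any():
                raise DataFormatError(f"marker column {m!r} has negative intensities")
        self.markers = tuple(self.markers)

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def image_ids(self) -> list[str]:
        return list(pd.unique(self.data["image_id"]))

    @property
    def has_phenotype(self) -> bool:
        return "phenotype" in self.data.columns

    def for_image(self, image_id: str) -> pd.DataFrame:
        return self.data[self.data["image_id"] == image_id]

    def expression(self) -> pd.DataFrame:
        """Cells x markers intensity matrix (indexed by cell_id)."""
        return self.data.set_index("cell_id")[list(self.markers)]

    def with_phenotype(self, labels) -> "CellTable":
        """Return a copy with a ``phenotype`` column (aligned to row order)."""
        df = self.data.copy()
        df["phenotype"] = np.asarray(labels, dtype=object)
        return CellTable(df, self.markers)


@dataclass
class RegionMetadata:
    """Per-core metadata: patient, region class, replicate index, core area."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _META_REQUIRED:
            if col not in df.columns:
                raise DataFormatError(f"metadata is missing required column {col!r}")
        if df["image_id"].duplicated().any():
            dup = df.loc[df["image_id"].duplicated(), "image_id"].iloc[0]
            raise DataIntegrityError(f"duplicate image_id {dup!r} in metadata")
        bad = set(df["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise DataFormatError(
                f"unknown region_class value(s) {sorted(bad)!r}; "
                f"expected one of {REGION_CLASSES}"
            )
        if "area_mm2" not in df.columns:
            df["area_mm2"] = DEFAULT_CORE_AREA_MM2
        df["area_mm2"] = df["area_mm2"].fillna(DEFAULT_CORE_AREA_MM2).astype(float)
        if (df["area_mm2"] <= 0).any():
            raise DataFormatError("area_mm2 must be positive")
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise DataFormatError("replicate index must be >= 1")

    @property
    def n_images(self) -> int:
        return len(self.data)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def regions(self) -> list[str]:
        return [r for r in REGION_CLASSES if r in set(self.data["region_class"])]

    def area_of(self, image_id: str) -> float:
        row = self.data[self.data["image_id"] == image_id]
        if row.empty:
            raise KeyError(image_id)
        return float(row["area_mm2"].iloc[0])


@dataclass
class ValidationReport:
    """Findings from cross-checking a cell table against its metadata."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_cells: int = 0
    n_images: int = 0
    n_patients: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cell_table(path) -> CellTable:
    """Read a segmented cell table from CSV.

    Marker columns are every column other than the required four and the
    optional ``phenotype`` column, preserved in file order.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "image_id": str})
    for col in _CELL_REQUIRED:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    markers = tuple(c for c in df.columns if c not in _CELL_REQUIRED and c != "phenotype")
    if not markers:
        raise DataFormatError(f"{path}: no marker columns found")
    return CellTable(df, markers)


def write_cell_table(cells: CellTable, path) -> None:
    cols = list(_CELL_REQUIRED) + list(cells.markers)
    if cells.has_phenotype:
        cols.append("phenotype")
    cells.data[cols].to_csv(path, index=False)


def read_region_metadata(path) -> RegionMetadata:
    """Read core metadata; a missing area column is filled with the disc default."""
    df = pd.read_csv(path, dtype={"image_id": str, "patient_id": str, "region_class": str})
    return RegionMetadata(df)


def write_region_metadata(meta: RegionMetadata, path) -> None:
    cols = list(_META_REQUIRED) + ["area_mm2"]
    meta.data[cols].to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a samples x features matrix written by :func:`write_feature_matrix`."""
    return pd.read_csv(path, index_col=["patient_id", "region_class"])


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label=["patient_id", "region_class"])


# ---------------------------------------------------------------------------
# dataset validation
# ---------------------------------------------------------------------------

def validate_dataset(
    cells: CellTable,
    meta: RegionMetadata,
    core_diameter_um: float = 1000.0,
) -> ValidationReport:
    """Cross-check a cell table against its metadata.

    Errors (pipeline must refuse to proceed): an image present in the cell
    table with no metadata row.  Warnings: coordinates outside the nominal
    core bounds, and images with zero cells.
    """
    report = ValidationReport(
        n_cells=cells.n_cells,
        n_images=meta.n_images,
        n_patients=meta.n_patients,
    )
    meta_images = set(meta.data["image_id"])
    cell_images = set(cells.image_ids)
    for img in sorted(cell_images - meta_images):
        report.errors.append(f"image {img!r} present in cells but missing from metadata")
    for img in sorted(meta_images - cell_images):
        report.warnings.append(f"image {img!r} has no cells")
    xy = cells.data[["x_um", "y_um"]].to_numpy(dtype=float)
    out = (xy < 0).any(axis=1) | (xy > core_diameter_um).any(axis=1)
    if out.any():
        bad_imgs = sorted(set(cells.data.loc[out, "image_id"]))
        for img in bad_imgs:
            report.warnings.append(
                f"image {img!r} has cells outside the nominal "
                f"[0, {core_diameter_um:g}] um core bounds"
            )
    return report
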