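"""Shared data model and tabular I/O.

The pipeline's universal currency is a pair of plain CSV tables:

* a **cell table** with one row per segmented cell
  (``cell_id, core_id, x_um, y_um, area_um2`` followed by one column per
  marker mean intensity, arbitrary fluorescence units), and
* a **core metadata table**
  (``core_id, patient_id, survival_5yr, treatment, survival_months,
  event_observed``).

Coordinates are Cartesian micrometres with a per-core local origin and y
increasing downward (image convention); all downstream geometry is
translation- and rotation-invariant, so the origin convention never matters.
``cell_id`` is dataset-global and is the deterministic tie-breaker
everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or has the wrong name."""


class IntegrityError(ValueError):
    """Referential integrity between cells and metadata is violated."""


#: The canonical phenotyping-marker set for this assay class: the 19 lineage
#: biomarkers used for unsupervised clustering. CD19 is part of the canonical
#: set but is typically dropped from panels whose CD19 staining fails QC.
CANONICAL_CLUSTERING_MARKERS: tuple[str, ...] = (
    "CD11b",
    "CD14",
    "CD19",
    "CD20",
    "CD21",
    "CD31",
    "CD3e",
    "CD4",
    "CD45",
    "CD57",
    "CD68",
    "CD8",
    "Collagen IV",
    "E-Cadherin",
    "FOXP3",
    "Pan-cytokeratin",
    "Podoplanin",
    "SMA",
    "Vimentin",
)

#: Default 30-marker analysis panel: 29 protein markers that pass staining QC
#: in the emulated assay plus the DAPI nuclear (DNA) channel. CD11c, CD163,
#: CD19 and LAG-3 are excluded (staining artifacts in the emulated study).
DEFAULT_PANEL_MARKERS: tuple[str, ...] = (
    "DAPI",
    "HLA-A",
    "CD34",
    "CD20",
    "CD68",
    "Vimentin",
    "CD8",
    "CD31",
    "E-Cadherin",
    "CD45",
    "SMA",
    "CD45RO",
    "CD3e",
    "Pan-cytokeratin",
    "CD44",
    "HLA-DR",
    "GZMB",
    "Collagen IV",
    "ICOS",
    "FOXP3",
    "CD4",
    "Ki67",
    "CD57",
    "CD21",
    "PD-L1",
    "CD14",
    "CD11b",
    "Podoplanin",
    "IDO1",
    "PD-1",
)

REQUIRED_CELL_COLUMNS = ("cell_id", "core_id", "x_um", "y_um", "area_um2")
REQUIRED_META_COLUMNS = (
    "core_id",
    "patient_id",
    "survival_5yr",
    "treatment",
    "survival_months",
    "event_observed",
)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel plus the subset used for phenotyping.

    Parameters
    ----------
    markers
        Ordered, unique marker names; one intensity column per name.
    clustering_markers
        Subset of ``markers`` used for clustering/phenotyping. Defaults to
        the intersection of the panel with the canonical 19-marker set.
    """

    markers: tuple[str, ...]
    clustering_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        if len(set(markers)) != len(markers):
            raise ValueError("marker names must be unique")
        clustering = tuple(self.clustering_markers)
        if not clustering:
            clustering = tuple(
                m for m in markers if m in CANONICAL_CLUSTERING_MARKERS
            )
        unknown = set(clustering) - set(markers)
        if unknown:
            raise ValueError(
                f"clustering markers not in panel: {sorted(unknown)}"
            )
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "clustering_markers", clustering)

    def __len__(self) -> int:
        return len(self.markers)

    def index_of(self, marker: str) -> int:
        return self.markers.index(marker)


def default_panel() -> MarkerPanel:
    """The default 30-marker panel (DAPI + 29 protein markers)."""
    return MarkerPanel(markers=DEFAULT_PANEL_MARKERS)


@dataclass
class Dataset:
    """A validated study: cell table, per-core metadata, marker panel.

    ``cells`` carries the required columns, one intensity column per panel
    marker, and optionally ``qc_pass``, ``cell_type``, ``cn_label`` plus any
    extra columns (carried through untouched).
    """

    cells: pd.DataFrame
    metadata: pd.DataFrame
    panel: MarkerPanel

    def __post_init__(self) -> None:
        validate_dataset(self)

    def marker_matrix(self) -> np.ndarray:
        """(n_cells, n_markers) float array in panel order."""
        return self.cells[list(self.panel.markers)].to_numpy(dtype=float)

    def cohort_of(self, core_id: str) -> str:
        row = self.metadata.loc[self.metadata["core_id"] == core_id]
        return str(row["survival_5yr"].iloc[0])


def validate_dataset(ds: Dataset) -> None:
    """Raise SchemaError/IntegrityError on any contract violation."""
    for col in REQUIRED_CELL_COLUMNS:
        if col not in ds.cells.columns:
            raise SchemaError(f"cell table missing required column {col!r}")
    for col in REQUIRED_META_COLUMNS:
        if col not in ds.metadata.columns:
            raise SchemaError(f"metadata missing required column {col!r}")
    for marker in ds.panel.markers:
        if marker not in ds.cells.columns:
            raise SchemaError(f"cell table missing marker column {marker!r}")

    if ds.cells["cell_id"].duplicated().any():
        raise IntegrityError("duplicate cell_id in cell table")
    if ds.metadata["core_id"].duplicated().any():
        raise IntegrityError("duplicate core_id in metadata")

    known = set(ds.metadata["core_id"].astype(str))
    present = set(ds.cells["core_id"].astype(str))
    orphans = present - known
    if orphans:
        raise IntegrityError(
            f"core_id values in cell table absent from metadata: "
            f"{sorted(orphans)}"
        )

    if len(ds.cells):
        if not np.all(np.isfinite(ds.cells[["x_um", "y_um"]].to_numpy(float))):
            raise IntegrityError("non-finite cell coordinates")
        if not (ds.cells["area_um2"].to_numpy(float) > 0).all():
            raise IntegrityError("cell area must be positive")


def read_dataset(
    cell_table_path: str | Path,
    metadata_path: str | Path,
    panel: MarkerPanel | None = None,
) -> Dataset:
    """Read and validate a dataset from its two CSV files.

    When ``panel`` is None the marker panel is inferred as every cell-table
    column after the required five that is not a known annotation column.
    Row order is preserved; unknown columns are carried through untouched.
    """
    cells = pd.read_csv(cell_table_path)
    metadata = pd.read_csv(metadata_path)
    if panel is None:
        annotation = {"qc_pass", "cell_type", "cn_label"}
        inferred = [
            c
            for c in cells.columns
            if c not in REQUIRED_CELL_COLUMNS and c not in annotation
        ]
        panel = MarkerPanel(markers=tuple(inferred))
    cells["core_id"] = cells["core_id"].astype(str)
    metadata["core_id"] = metadata["core_id"].astype(str)
    metadata["patient_id"] = metadata["patient_id"].astype(str)
    return Dataset(cells=cells, metadata=metadata, panel=panel)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as ``cells.csv`` + ``metadata.csv``.

    Column order is documented and deterministic: the required columns, the
    panel markers in panel order, then any annotation/extra columns in their
    current order. Two writes of the same dataset yield identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lead = [c for c in REQUIRED_CELL_COLUMNS]
    marker_cols = list(ds.panel.markers)
    rest = [c for c in ds.cells.columns if c not in lead + marker_cols]
    cells_path = out / "cells.csv"
    meta_path = out / "metadata.csv"
    ds.cells[lead + marker_cols + rest].to_csv(cells_path, index=False)
    ds.metadata[
        [c for c in REQUIRED_META_COLUMNS]
        + [c for c in ds.metadata.columns if c not in REQUIRED_META_COLUMNS]
    ].to_csv(meta_path, index=False)
    return {"cells": cells_path, "metadata": meta_path}
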