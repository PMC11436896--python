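"""Cellular neighborhoods: k-NN window composition + k-means.

Every annotated cell's spatial window is the cell itself plus its k nearest
neighbors (Euclidean centroid distance) within the same core; the window's
cell-type composition (counts / (k+1)) is that cell's row in the
composition matrix. Pooling windows across cores and k-means clustering
them into a predefined number of groups (default 12) yields the conserved
cellular neighborhoods (CNs); each cell's CN label is the cluster of its
window.

The CN profile heatmap convention: row-normalize the k-means centroids to
proportions, divide each column by the global abundance of that cell type,
then log2-transform with a small pseudocount, so a CN whose composition
equals the global mixture maps to a ~0 row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans


@dataclass
class NeighborhoodModel:
    """Fitted k-means CN model over k-NN window compositions."""

    k: int
    n_neighborhoods: int
    cell_types: tuple[str, ...]
    centroids: np.ndarray  # (n_neighborhoods, n_types)
    seed: int

    def assign(self, comp: pd.DataFrame) -> np.ndarray:
        """CN label for each composition row (nearest centroid)."""
        x = comp[list(self.cell_types)].to_numpy(float)
        d2 = ((x[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def centroid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.centroids,
            index=[f"CN{i}" for i in range(self.n_neighborhoods)],
            columns=list(self.cell_types),
        )


def neighborhood_windows(
    cells: pd.DataFrame,
    k: int = 10,
    cell_types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """k-NN window composition matrix over all cores.

    Returns a DataFrame indexed by cell_id with one column per cell type;
    each row is the type composition of the cell's window (itself + its k
    nearest neighbors in the same core) and sums to 1. Cores with <= k
    cells are skipped with a warning.
    """
    if "cell_type" not in cells.columns:
        raise ValueError("cells lack cell_type labels")
    if cell_types is None:
        cell_types = tuple(sorted(cells["cell_type"].unique()))
    type_index = {t: i for i, t in enumerate(cell_types)}
    rows: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    for core_id, sub in cells.groupby("core_id", sort=True):
        n = len(sub)
        if n <= k:
            warnings.warn(
                f"core {core_id}: {n} cells <= k={k}; skipped from windows"
            )
            continue
        pts = sub[["x_um", "y_um"]].to_numpy(float)
        tree = cKDTree(pts)
        # query k+1 including the cell itself (distance 0)
        _, nbr = tree.query(pts, k=k + 1)
        tcodes = sub["cell_type"].map(type_index).to_numpy()
        window_types = tcodes[nbr]  # (n, k+1)
        comp = np.zeros((n, len(cell_types)))
        for j in range(k + 1):
            np.add.at(comp, (np.arange(n), window_types[:, j]), 1.0)
        rows.append(comp / (k + 1))
        ids.append(sub["cell_id"].to_numpy())
    if not rows:
        return pd.DataFrame(columns=list(cell_types))
    out = pd.DataFrame(
        np.vstack(rows), index=np.concatenate(ids), columns=list(cell_types)
    )
    out.index.name = "cell_id"
    return out


def fit_neighborhoods(
    comp: pd.DataFrame,
    n_neighborhoods: int = 12,
    k: int = 10,
    seed: int = 0,
) -> tuple[NeighborhoodModel, np.ndarray]:
    """k-means over pooled composition rows; returns (model, labels).

    k-means++ initialization with 10 restarts; deterministic under a fixed
    seed. Raises if there are fewer rows than requested neighborhoods.
    """
    if len(comp) < n_neighborhoods:
        raise ValueError(
            f"{len(comp)} composition rows < n_neighborhoods={n_neighborhoods}"
        )
    km = KMeans(
        n_clusters=n_neighborhoods,
        init="k-means++",
        n_init=10,
        random_state=seed,
    )
    labels = km.fit_predict(comp.to_numpy(float))
    model = NeighborhoodModel(
        k=k,
        n_neighborhoods=n_neighborhoods,
        cell_types=tuple(comp.columns),
        centroids=km.cluster_centers_,
        seed=seed,
    )
    return model, labels


def cn_proportions(
    cells: pd.DataFrame, cn_labels: pd.Series | None = None
) -> pd.DataFrame:
    """Per-core CN proportion table (rows sum to 1).

    ``cn_labels`` maps cell_id -> CN label; alternatively ``cells`` may
    already carry a ``cn_label`` column.
    """
    df = cells
    if cn_labels is not None:
        df = cells.copy()
        df["cn_label"] = df["cell_id"].map(cn_labels)
    if "cn_label" not in df.columns:
        raise ValueError("no CN labels provided")
    df = df.dropna(subset=["cn_label"])
    counts = (
        df.groupby(["core_id", "cn_label"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"CN{int(c)}" for c in props.columns]
    return props


def cn_profile_matrix(
    model: NeighborhoodModel,
    global_abundance: pd.Series,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Row/column-scaled log2 CN enrichment profile.

    Centroid rows are renormalized to proportions, each column divided by
    the global abundance of that cell type, then log2(x + eps). Types with
    zero global abundance are dropped with a warning. A CN whose
    composition equals the global mixture maps to a ~0 row.
    """
    cent = model.centroid_frame()
    cent = cent.clip(lower=0.0)
    cent = cent.div(cent.sum(axis=1), axis=0)
    ab = global_abundance.reindex(cent.columns)
    zero = ab.index[(ab.isna()) | (ab <= 0)]
    if len(zero):
        warnings.warn(
            f"dropping cell types with zero global abundance: {list(zero)}"
        )
        cent = cent.drop(columns=list(zero))
        ab = ab.drop(list(zero))
    ratio = cent.div(ab, axis=1)
    return np.log2(ratio + eps)


def voronoi_export(
    cells: pd.DataFrame,
    area_max: float = 400.0,
) -> pd.DataFrame:
    """(cell_id, core_id, x_um, y_um, cn_label) table for Voronoi rendering,
    restricted to cells passing the area filter used by the contact graphs."""
    keep = cells["area_um2"].to_numpy(float) <= area_max
    cols = ["cell_id", "core_id", "x_um", "y_um", "cn_label"]
    return cells.loc[keep, cols].reset_index(drop=True)
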