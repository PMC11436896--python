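"""Marker normalization, unsupervised clustering, and cluster annotation.

Phenotyping follows the convention of CODEX/PhenoCycler-class analyses:

1. normalize intensities (arcsinh transform, per-marker z-score, clipped),
2. Leiden-cluster cells on a k-NN graph built from the lineage
   (clustering) markers at resolution 1,
3. optionally subcluster each parent cluster on a small parameter grid
   (neighbors in {50, 30, 10}, resolution in {0.5, 0.1}),
4. annotate each cluster by gating its mean normalized profile against an
   ordered set of required-positive / required-negative marker rules.

The shipped rule set encodes the standard iTME phenotype definitions for
this panel (e.g. MDSC = CD14+ HLA-DR-, TAM = CD68+ HLA-DR-, NK = CD57+,
Tumor = Vimentin+ fallback). Rules are ordered specific-to-general
(structural, lymphoid, myeloid, marker-only classes, Tumor) and the first
rule whose positives all exceed the threshold and whose negatives all fall
below it wins; a cluster matching no rule is "Undefined". Annotation uses
the full panel (functional markers such as HLA-DR or PD-1 are gating
markers even though they are not clustering markers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ositme.io_model import MarkerPanel


@dataclass(frozen=True)
class NormalizationParams:
    """arcsinh cofactor and z-score clip bound (in z-units)."""

    arcsinh_cofactor: float = 5.0
    zscore_clip: float = 3.0

    def __post_init__(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh cofactor must be positive")


@dataclass(frozen=True)
class ClusteringParams:
    graph_neighbors: int = 30
    resolution: float = 1.0
    umap_min_dist: float = 1e-4  # diagnostic embedding only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.graph_neighbors < 2:
            raise ValueError("graph_neighbors must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


SUBCLUSTER_NEIGHBOR_GRID = (50, 30, 10)
SUBCLUSTER_RESOLUTION_GRID = (0.5, 0.1)


@dataclass(frozen=True)
class SubclusterParams:
    """Per-parent refinement parameters, restricted to the standard grid
    unless ``allow_off_grid`` is set."""

    graph_neighbors: int = 10
    resolution: float = 0.1
    umap_min_dist: float = 1e-4
    seed: int = 0
    allow_off_grid: bool = False

    def __post_init__(self) -> None:
        if not self.allow_off_grid:
            if self.graph_neighbors not in SUBCLUSTER_NEIGHBOR_GRID:
                raise ValueError(
                    f"subcluster neighbors must be one of "
                    f"{SUBCLUSTER_NEIGHBOR_GRID}"
                )
            if self.resolution not in SUBCLUSTER_RESOLUTION_GRID:
                raise ValueError(
                    f"subcluster resolution must be one of "
                    f"{SUBCLUSTER_RESOLUTION_GRID}"
                )


@dataclass(frozen=True)
class GatingRule:
    cell_type: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()


@dataclass(frozen=True)
class GatingRuleSet:
    """Ordered gating rules plus the positivity threshold (z-units) applied
    to cluster-mean normalized expression."""

    rules: tuple[GatingRule, ...]
    threshold: float = 0.5
    fallback: str = "Undefined"

    def markers_used(self) -> set[str]:
        used: set[str] = set()
        for r in self.rules:
            used |= set(r.positive) | set(r.negative)
        return used

    def validate_against(self, panel: MarkerPanel) -> None:
        missing = self.markers_used() - set(panel.markers)
        if missing:
            raise ValueError(f"gating markers not in panel: {sorted(missing)}")

    def call(self, profile: pd.Series) -> str:
        """Label one cluster-mean profile (marker -> normalized mean)."""
        for r in self.rules:
            if all(profile[m] > self.threshold for m in r.positive) and all(
                profile[m] < self.threshold for m in r.negative
            ):
                return r.cell_type
        return self.fallback


def default_gating_rules() -> GatingRuleSet:
    """The shipped iTME phenotype definitions for the default panel.

    Ordered structural -> lymphoid -> myeloid -> marker-only -> Tumor, so
    that Vimentin positivity is the fallback mesenchymal (Tumor) call.
    """
    r = GatingRule
    rules = (
        # structural / stromal
        r("Epithelial", ("Pan-cytokeratin", "E-Cadherin")),
        r("Endothelial", ("CD31", "CD34")),
        r("Lymphatic Endothelial", ("Podoplanin",), ("CD20", "CD21", "CD3e")),
        r("Fibroblast", ("Collagen IV",)),
        r("Fibroblast", ("SMA",)),
        # lymphoid, specific before general
        r("PD-1+ Treg", ("CD3e", "CD4", "FOXP3", "PD-1")),
        r("Treg", ("CD3e", "CD4", "FOXP3")),
        r("PD-1+ Memory Helper T cell", ("CD3e", "CD4", "CD45RO", "PD-1")),
        r("Memory Helper T cell", ("CD3e", "CD4", "CD45RO")),
        r("PD-1+ Helper T cell", ("CD3e", "CD4", "PD-1")),
        r("Helper T cell", ("CD3e", "CD4")),
        r("PD-1+ Memory Cytotoxic T cell", ("CD3e", "CD8", "CD45RO", "PD-1")),
        r("Memory Cytotoxic T cell", ("CD3e", "CD8", "CD45RO")),
        r("GZMB+ Cytotoxic T cell", ("CD3e", "CD8", "GZMB")),
        r("PD-1+ Cytotoxic T cell", ("CD3e", "CD8", "PD-1")),
        r("Cytotoxic T cell", ("CD3e", "CD8")),
        r("T Lymphocyte", ("CD3e",)),
        r("PDPN+ CD21+ B cell", ("CD20", "CD21", "Podoplanin")),
        r("CD21+ B cell", ("CD20", "CD21")),
        r("B cell", ("CD20",)),
        r("NK cell", ("CD57",), ("CD3e",)),
        # myeloid
        r("Macrophage", ("CD68", "HLA-DR"), ("CD14",)),
        r("TAM", ("CD68",), ("HLA-DR", "CD14")),
        r("Mono-Mac", ("CD14", "CD68")),
        r("Monocyte", ("CD14", "HLA-DR"), ("CD68",)),
        r("MDSC", ("CD14",), ("HLA-DR", "CD68")),
        r("Neutrophil", ("CD11b",), ("CD14", "CD68")),
        # marker-only classes (no defining lineage marker)
        r("IDO1+ HLA-DR+ cell", ("IDO1", "HLA-DR")),
        r("PD-1+ IDO1+ cell", ("PD-1", "IDO1")),
        r("IDO1+ cell", ("IDO1",)),
        r("HLA-A+ cell", ("HLA-A",)),
        r("CD44+ cell", ("CD44",)),
        r("Proliferating", ("Ki67",)),
        # mesenchymal fallback
        r("Tumor", ("Vimentin",)),
    )
    return GatingRuleSet(rules=rules)


def normalize_expression(
    cells: pd.DataFrame,
    panel: MarkerPanel,
    params: NormalizationParams = NormalizationParams(),
) -> pd.DataFrame:
    """arcsinh(x / cofactor), per-marker population z-score, clipped.

    Constant markers (zero variance) map to all-zero columns. Returns a
    DataFrame indexed like ``cells`` with one column per panel marker.
    """
    x = cells[list(panel.markers)].to_numpy(dtype=float)
    if x.size == 0:
        return pd.DataFrame(
            np.zeros_like(x), index=cells.index, columns=list(panel.markers)
        )
    t = np.arcsinh(x / params.arcsinh_cofactor)
    mu = t.mean(axis=0)
    sd = t.std(axis=0)  # population SD
    z = np.where(sd > 0, (t - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    z = np.clip(z, -params.zscore_clip, params.zscore_clip)
    return pd.DataFrame(z, index=cells.index, columns=list(panel.markers))


def _leiden(
    x: np.ndarray, n_neighbors: int, resolution: float, seed: int
) -> np.ndarray:
    import scanpy as sc
    from anndata import AnnData

    if len(x) < n_neighbors + 1:
        raise ValueError(
            f"need at least {n_neighbors + 1} cells for a "
            f"{n_neighbors}-nearest-neighbor graph; got {len(x)} "
            f"(use a smaller graph_neighbors)"
        )
    adata = AnnData(X=np.asarray(x, dtype=np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(
            adata, n_neighbors=n_neighbors, use_rep="X", random_state=seed
        )
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
        )
    labels = adata.obs["leiden"].astype(int).to_numpy()
    # contiguous integer labels ordered by first occurrence
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def cluster_cells(
    normalized: pd.DataFrame,
    panel: MarkerPanel,
    params: ClusteringParams = ClusteringParams(),
) -> np.ndarray:
    """Leiden community detection on a k-NN graph in clustering-marker space.

    ``normalized`` is the full normalized matrix; only the panel's
    clustering markers enter the graph. Deterministic under a fixed seed.
    """
    x = normalized[list(panel.clustering_markers)].to_numpy(dtype=float)
    return _leiden(x, params.graph_neighbors, params.resolution, params.seed)


def subcluster(
    normalized_subset: pd.DataFrame,
    markers: list[str] | tuple[str, ...],
    params: SubclusterParams = SubclusterParams(),
) -> np.ndarray:
    """Refine one parent cluster on a chosen marker subset.

    Returns labels partitioning exactly the parent's cells.
    """
    x = normalized_subset[list(markers)].to_numpy(dtype=float)
    return _leiden(x, params.graph_neighbors, params.resolution, params.seed)


def annotate_clusters(
    cluster_means: pd.DataFrame, rules: GatingRuleSet
) -> dict[object, str]:
    """Gate cluster-mean normalized profiles to cell-type labels.

    ``cluster_means``: one row per cluster, one column per marker.
    """
    return {idx: rules.call(cluster_means.loc[idx]) for idx in cluster_means.index}


def cluster_mean_profiles(
    normalized: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Mean normalized expression per cluster (rows = cluster labels)."""
    df = normalized.copy()
    df["_cluster"] = labels
    return df.groupby("_cluster").mean()


def assign_cell_types(
    cells: pd.DataFrame,
    normalized: pd.DataFrame,
    labels: np.ndarray,
    rules: GatingRuleSet,
) -> pd.DataFrame:
    """Cluster -> gate -> write a ``cell_type`` column; returns a copy."""
    means = cluster_mean_profiles(normalized, labels)
    mapping = annotate_clusters(means, rules)
    out = cells.copy()
    out["cell_type"] = [mapping[c] for c in labels]
    return out


def cell_type_proportions(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-core cell-type proportion table (rows sum to 1).

    Rows = core_id, columns = cell types present anywhere in the table.
    """
    if "cell_type" not in cells.columns:
        raise ValueError("cells lack cell_type labels")
    counts = (
        cells.groupby(["core_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns.name = None
    return props
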