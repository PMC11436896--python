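"""Median neighbor distances and the composite spatial score.

For each core, the directed nearest-neighbor distance from every cell of a
source type to the closest cell of a target type is computed (when source
and target coincide, a cell's own position is excluded); the population
summary is the median over source cells.

The per-core spatial score for a suppressor population S in {Treg, TAM,
MDSC} is

    score_S = median_S(d(S -> NK)) / median(d(Tumor -> NK))

and the composite score is the arithmetic mean of the defined component
scores. A larger score means immunosuppressive cells sit farther from NK
cells relative to how close NK cells are to tumor cells — a geometric
proxy for freer effector activity. Components whose populations are
missing (or whose denominator is zero) are flagged undefined and dropped
from the mean rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_SUPPRESSORS = ("Treg", "TAM", "MDSC")


@dataclass
class SpatialScoreResult:
    core_id: str
    median_distances: dict[str, float]  # "Treg->NK", ..., "Tumor->NK" (um)
    component_scores: dict[str, float]  # suppressor -> ratio (NaN undefined)
    os_spatial_score: float  # NaN when no component defined
    defined: dict[str, bool]


def median_neighbor_distance(
    core_cells: pd.DataFrame, source_type: str, target_type: str
) -> float:
    """Median over source cells of the distance to the nearest target cell.

    Returns NaN when either population is absent. With source == target a
    cell's own position is excluded (NaN for a single cell).
    """
    src = core_cells.loc[core_cells["cell_type"] == source_type]
    tgt = core_cells.loc[core_cells["cell_type"] == target_type]
    if len(src) == 0 or len(tgt) == 0:
        return float("nan")
    same = source_type == target_type
    if same and len(tgt) < 2:
        return float("nan")
    tree = cKDTree(tgt[["x_um", "y_um"]].to_numpy(float))
    pts = src[["x_um", "y_um"]].to_numpy(float)
    if same:
        d, _ = tree.query(pts, k=2)
        nearest = d[:, 1]
    else:
        nearest, _ = tree.query(pts, k=1)
    return float(np.median(nearest))


def spatial_score(
    core_cells: pd.DataFrame,
    suppressor_type: str,
    nk_label: str = "NK cell",
    tumor_label: str = "Tumor",
) -> float:
    """suppressor->NK median distance over Tumor->NK median distance.

    NaN when a population is missing or the denominator is zero.
    """
    num = median_neighbor_distance(core_cells, suppressor_type, nk_label)
    den = median_neighbor_distance(core_cells, tumor_label, nk_label)
    if math.isnan(num) or math.isnan(den) or den == 0.0:
        return float("nan")
    return num / den


def os_spatial_score(
    core_cells: pd.DataFrame,
    suppressors: tuple[str, ...] = DEFAULT_SUPPRESSORS,
    nk_label: str = "NK cell",
    tumor_label: str = "Tumor",
) -> SpatialScoreResult:
    """Composite spatial score for one core.

    The composite is the mean of the defined component scores; which
    components were defined is recorded. NaN composite when none is.
    """
    core_id = str(core_cells["core_id"].iloc[0]) if len(core_cells) else ""
    dists = {
        f"{s}->{nk_label}": median_neighbor_distance(core_cells, s, nk_label)
        for s in suppressors
    }
    dists[f"{tumor_label}->{nk_label}"] = median_neighbor_distance(
        core_cells, tumor_label, nk_label
    )
    comp = {
        s: spatial_score(core_cells, s, nk_label=nk_label, tumor_label=tumor_label)
        for s in suppressors
    }
    defined = {s: not math.isnan(v) for s, v in comp.items()}
    vals = [v for v in comp.values() if not math.isnan(v)]
    composite = float(np.mean(vals)) if vals else float("nan")
    return SpatialScoreResult(
        core_id=core_id,
        median_distances=dists,
        component_scores=comp,
        os_spatial_score=composite,
        defined=defined,
    )


def spatial_score_table(
    cells: pd.DataFrame,
    suppressors: tuple[str, ...] = DEFAULT_SUPPRESSORS,
    nk_label: str = "NK cell",
    tumor_label: str = "Tumor",
) -> pd.DataFrame:
    """Per-core table of component and composite spatial scores."""
    rows = []
    for core_id, sub in cells.groupby("core_id", sort=True):
        res = os_spatial_score(
            sub, suppressors=suppressors, nk_label=nk_label, tumor_label=tumor_label
        )
        row = {"core_id": str(core_id)}
        for key, v in res.median_distances.items():
            row[f"d_{key}"] = v
        for s, v in res.component_scores.items():
            row[f"score_{s}"] = v
        row["os_spatial_score"] = res.os_spatial_score
        rows.append(row)
    return pd.DataFrame(rows).set_index("core_id")
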