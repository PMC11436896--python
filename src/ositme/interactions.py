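"""Delaunay cell-cell contact graphs and interaction frequencies.

Direct cellular contacts within a core are proxied by the edges of the
Delaunay triangulation of cell centroids, after two filters:

* cells larger than the segmentation area threshold (default 400 um^2) are
  excluded before triangulating, and
* triangles whose minimum internal angle falls below a threshold (default
  45 degrees) are discarded — sliver triangles fabricate long-range
  "contacts" between cells that are not neighbors in the tissue.

The per-core interaction frequency of an unordered cell-type pair is the
number of retained edges joining the two types divided by the total number
of retained edges (same-type contacts included), so frequencies sum to 1
over unordered pairs within a core.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError


@dataclass
class ContactGraph:
    """Per-core undirected contact edges after area/angle filtering."""

    core_id: str
    cell_ids: np.ndarray  # nodes (cells surviving the area filter)
    edges: np.ndarray  # (n_edges, 2) cell_id pairs, each sorted

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _triangle_min_angles(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Minimum internal angle (degrees) of each triangle."""
    p = points[simplices]  # (n, 3, 2)
    a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    b = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    angles = np.empty((len(simplices), 3))
    for i, (opp, s1, s2) in enumerate(((a, b, c), (b, a, c), (c, a, b))):
        cos = (s1**2 + s2**2 - opp**2) / (2 * s1 * s2)
        angles[:, i] = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return angles.min(axis=1)


def build_contact_graph(
    core_cells: pd.DataFrame,
    area_max: float = 400.0,
    min_angle: float = 45.0,
) -> ContactGraph:
    """Delaunay contact graph for one core's cells.

    Cells with ``area_um2 > area_max`` are dropped first; triangles with any
    internal angle below ``min_angle`` are discarded; the edge set is the
    union of edges of surviving triangles. Fewer than 3 usable cells (or a
    degenerate, collinear configuration) yields an empty graph with a
    warning rather than an error.
    """
    core_id = str(core_cells["core_id"].iloc[0]) if len(core_cells) else ""
    usable = core_cells.loc[
        core_cells["area_um2"].to_numpy(float) <= area_max
    ]
    ids = usable["cell_id"].to_numpy()
    pts = usable[["x_um", "y_um"]].to_numpy(float)
    empty = np.zeros((0, 2), dtype=ids.dtype if len(ids) else int)
    if len(usable) < 3:
        warnings.warn(f"core {core_id}: fewer than 3 usable cells; empty graph")
        return ContactGraph(core_id=core_id, cell_ids=ids, edges=empty)
    try:
        tri = Delaunay(pts)
    except QhullError:
        warnings.warn(f"core {core_id}: degenerate geometry; empty graph")
        return ContactGraph(core_id=core_id, cell_ids=ids, edges=empty)
    keep = _triangle_min_angles(pts, tri.simplices) >= min_angle
    simplices = tri.simplices[keep]
    if len(simplices) == 0:
        return ContactGraph(core_id=core_id, cell_ids=ids, edges=empty)
    e = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    e = np.sort(e, axis=1)
    e = np.unique(e, axis=0)
    edges = np.sort(ids[e], axis=1)
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
    return ContactGraph(core_id=core_id, cell_ids=ids, edges=edges)


def interaction_frequencies(
    graph: ContactGraph, cell_types: pd.Series | dict
) -> pd.DataFrame:
    """Symmetric cell-type x cell-type contact frequency matrix.

    ``cell_types`` maps cell_id -> type label; every node must be labeled.
    Entries are edge counts between the two types divided by the total edge
    count; the sum over unordered type pairs (diagonal included once) is 1
    whenever any edge exists. An empty graph yields a zero matrix.
    """
    mapping = dict(cell_types) if not isinstance(cell_types, dict) else cell_types
    unlabeled = [cid for cid in graph.cell_ids if cid not in mapping]
    if unlabeled:
        raise ValueError(
            f"core {graph.core_id}: {len(unlabeled)} unlabeled node(s), "
            f"e.g. cell_id {unlabeled[0]}"
        )
    types = sorted({mapping[cid] for cid in graph.cell_ids})
    mat = pd.DataFrame(0.0, index=types, columns=types)
    if graph.n_edges == 0:
        return mat
    idx = {t: i for i, t in enumerate(types)}
    counts = np.zeros((len(types), len(types)))
    for u, v in graph.edges:
        i, j = idx[mapping[u]], idx[mapping[v]]
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    freq = counts / graph.n_edges
    return pd.DataFrame(freq, index=types, columns=types)


def chord_export(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (type1, type2, frequency) table, descending frequency.

    One row per unordered type pair with nonzero frequency; suitable input
    for external chord-diagram rendering.
    """
    rows = []
    for t1, t2 in itertools.combinations_with_replacement(matrix.index, 2):
        f = matrix.loc[t1, t2]
        if f > 0:
            rows.append((t1, t2, float(f)))
    out = pd.DataFrame(rows, columns=["type1", "type2", "frequency"])
    return out.sort_values(
        "frequency", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def interaction_feature_table(
    cells: pd.DataFrame,
    area_max: float = 400.0,
    min_angle: float = 45.0,
) -> pd.DataFrame:
    """Per-core interaction-frequency feature table over all cores.

    Rows = core_id; columns = "t1|t2" unordered type-pair labels over the
    global type alphabet; missing pairs are 0.
    """
    records = {}
    for core_id, sub in cells.groupby("core_id", sort=True):
        g = build_contact_graph(sub, area_max=area_max, min_angle=min_angle)
        mapping = dict(zip(sub["cell_id"], sub["cell_type"]))
        mat = interaction_frequencies(g, mapping)
        rec = {}
        for t1, t2 in itertools.combinations_with_replacement(mat.index, 2):
            rec[f"{t1}|{t2}"] = float(mat.loc[t1, t2])
        records[str(core_id)] = rec
    out = pd.DataFrame.from_dict(records, orient="index").fillna(0.0)
    out.index.name = "core_id"
    return out.sort_index().sort_index(axis=1)
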