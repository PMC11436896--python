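"""Cell quality control.

Four per-cell metrics decide whether a segmented cell enters the analysis:

* **area** — abnormally small or large cells are segmentation artifacts;
  the upper default (400 um^2) matches the segmentation area threshold.
* **dna_signal** — mean intensity of the DNA (DAPI) channel; cells without
  nuclear signal are debris.
* **signal_sum** — total intensity over all marker channels; poorly stained
  regions are low, staining artifacts abnormally high.
* **signal_cv** — coefficient of variation of the per-cell marker intensity
  vector (population standard deviation / mean, 0 when the mean is 0);
  artifacts tend to light up a single channel, giving extreme CV.

The metrics are stated by the assay platform; the cutoffs are this
package's documented, overridable defaults. Percentile rules are evaluated
per core so they track per-core staining variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ositme.io_model import Dataset, MarkerPanel


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs for the four QC rules.

    ``dna_signal_min_pct``, ``signal_sum_low_pct`` and
    ``signal_sum_high_pct`` are per-core percentiles in [0, 100];
    ``area_min``/``area_max`` are absolute um^2 bounds and ``cv_max`` an
    absolute bound on the intensity CV.
    """

    area_min: float = 30.0
    area_max: float = 400.0
    dna_signal_min_pct: float = 1.0
    signal_sum_low_pct: float = 1.0
    signal_sum_high_pct: float = 99.0
    cv_max: float = 2.0

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be < area_max")
        for p in (
            self.dna_signal_min_pct,
            self.signal_sum_low_pct,
            self.signal_sum_high_pct,
        ):
            if not 0.0 <= p <= 100.0:
                raise ValueError("percentiles must be within [0, 100]")


def compute_qc_metrics(
    cells: pd.DataFrame, panel: MarkerPanel, dna_marker: str = "DAPI"
) -> pd.DataFrame:
    """Per-cell QC metric table aligned with ``cells``.

    Returns columns ``cell_id, core_id, area, dna_signal, signal_sum,
    signal_cv``. ``signal_sum`` and ``signal_cv`` are computed over all
    panel markers (including the DNA channel, which is part of the stained
    panel). Empty input yields an empty table.
    """
    if dna_marker not in panel.markers:
        raise ValueError(f"DNA marker {dna_marker!r} not in panel")
    out = pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "core_id": cells["core_id"].to_numpy(),
            "area": cells["area_um2"].to_numpy(dtype=float),
        }
    )
    x = cells[list(panel.markers)].to_numpy(dtype=float)
    if len(cells) == 0:
        out["dna_signal"] = np.zeros(0)
        out["signal_sum"] = np.zeros(0)
        out["signal_cv"] = np.zeros(0)
        return out
    out["dna_signal"] = cells[dna_marker].to_numpy(dtype=float)
    out["signal_sum"] = x.sum(axis=1)
    mean = x.mean(axis=1)
    sd = x.std(axis=1)  # population (n-denominator) SD
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    out["signal_cv"] = cv
    return out


@dataclass(frozen=True)
class ResolvedQCThresholds:
    """Percentile rules resolved to absolute per-core cutoffs.

    Resolving once and reusing the result makes filtering an exact fixed
    point: re-filtering an already-filtered table changes nothing.
    """

    area_min: float
    area_max: float
    cv_max: float
    dna_lo: dict
    sum_lo: dict
    sum_hi: dict


def resolve_thresholds(
    metrics: pd.DataFrame, thr: QCThresholds = QCThresholds()
) -> ResolvedQCThresholds:
    """Turn percentile rules into absolute per-core cutoffs.

    Order-statistic percentile methods ("lower"/"higher") are used so the
    cutoffs are attained data values and small cores keep their
    extreme-but-nominal cells at the 1st/99th defaults.
    """
    dna = metrics["dna_signal"].to_numpy(float)
    ssum = metrics["signal_sum"].to_numpy(float)
    core_ids = metrics["core_id"].to_numpy()
    dna_lo, sum_lo, sum_hi = {}, {}, {}
    for core in pd.unique(core_ids):
        m = core_ids == core
        dna_lo[core] = float(
            np.percentile(dna[m], thr.dna_signal_min_pct, method="lower")
        )
        sum_lo[core] = float(
            np.percentile(ssum[m], thr.signal_sum_low_pct, method="lower")
        )
        sum_hi[core] = float(
            np.percentile(ssum[m], thr.signal_sum_high_pct, method="higher")
        )
    return ResolvedQCThresholds(
        area_min=thr.area_min,
        area_max=thr.area_max,
        cv_max=thr.cv_max,
        dna_lo=dna_lo,
        sum_lo=sum_lo,
        sum_hi=sum_hi,
    )


def filter_cells(
    cells: pd.DataFrame,
    metrics: pd.DataFrame,
    thr: QCThresholds | ResolvedQCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four QC rules; return (passing cells, rejection report).

    A cell passes iff it satisfies every rule; the report counts rejections
    per rule (a cell violating several rules counts under each). Percentile
    rules are evaluated within each core; pass a ``ResolvedQCThresholds``
    (from :func:`resolve_thresholds`) to pin them to absolute cutoffs.
    """
    if len(cells) != len(metrics):
        raise ValueError("metrics not aligned with cells")
    if len(cells) == 0:
        report = {"area": 0, "dna_signal": 0, "signal_sum": 0, "cv": 0}
        out = cells.copy()
        out["qc_pass"] = pd.Series(dtype=bool)
        return out, report
    if isinstance(thr, QCThresholds):
        thr = resolve_thresholds(metrics, thr)

    area = metrics["area"].to_numpy(float)
    ok_area = (area >= thr.area_min) & (area <= thr.area_max)

    dna = metrics["dna_signal"].to_numpy(float)
    ssum = metrics["signal_sum"].to_numpy(float)
    ok_dna = np.ones(len(cells), dtype=bool)
    ok_sum = np.ones(len(cells), dtype=bool)
    core_ids = metrics["core_id"].to_numpy()
    for core in pd.unique(core_ids):
        m = core_ids == core
        ok_dna[m] = dna[m] >= thr.dna_lo[core]
        ok_sum[m] = (ssum[m] >= thr.sum_lo[core]) & (ssum[m] <= thr.sum_hi[core])

    cv = metrics["signal_cv"].to_numpy(float)
    ok_cv = cv <= thr.cv_max

    passing = ok_area & ok_dna & ok_sum & ok_cv
    report = {
        "area": int((~ok_area).sum()),
        "dna_signal": int((~ok_dna).sum()),
        "signal_sum": int((~ok_sum).sum()),
        "cv": int((~ok_cv).sum()),
    }
    out = cells.copy()
    out["qc_pass"] = passing
    return out.loc[passing].copy(), report


def apply_qc(
    ds: Dataset, thr: QCThresholds = QCThresholds(), dna_marker: str = "DAPI"
) -> tuple[Dataset, dict[str, int]]:
    """Convenience wrapper: QC a whole dataset, keep passing cells."""
    metrics = compute_qc_metrics(ds.cells, ds.panel, dna_marker=dna_marker)
    passing, report = filter_cells(ds.cells, metrics, thr)
    return Dataset(cells=passing.reset_index(drop=True),
                   metadata=ds.metadata, panel=ds.panel), report
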