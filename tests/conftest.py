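"""Shared fixtures: small synthetic studies and toy tables."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ositme.io_model import Dataset, MarkerPanel
from ositme.synthetic import SimConfig, simulate_dataset


def small_config(**overrides) -> SimConfig:
    """Study-shaped (26 cores / 12 patients) but with small cores so the
    whole suite stays fast; geometry and mixtures are the defaults."""
    base = dict(cells_per_core=(250, 400), seed=11)
    base.update(overrides)
    return replace(SimConfig(), **base)


@pytest.fixture(scope="session")
def small_study():
    """One small study-shaped dataset plus its planted truth."""
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def typed_cells(small_study):
    """Cell table carrying the *true* phenotype labels (bypasses
    clustering so spatial modules can be tested in isolation)."""
    ds, truth = small_study
    cells = ds.cells.merge(
        truth.cells[["cell_id", "true_type", "true_niche"]], on="cell_id"
    )
    return cells.rename(columns={"true_type": "cell_type"})


@pytest.fixture()
def toy_panel() -> MarkerPanel:
    return MarkerPanel(markers=("M1", "M2"), clustering_markers=("M1", "M2"))


@pytest.fixture()
def toy_dataset(toy_panel) -> Dataset:
    cells = pd.DataFrame(
        {
            "cell_id": [0, 1, 2],
            "core_id": ["A", "A", "B"],
            "x_um": [0.0, 10.0, 5.0],
            "y_um": [0.0, 0.0, 5.0],
            "area_um2": [100.0, 120.0, 90.0],
            "M1": [1.0, 2.0, 3.0],
            "M2": [4.0, 5.0, 6.0],
        }
    )
    metadata = pd.DataFrame(
        {
            "core_id": ["A", "B"],
            "patient_id": ["P1", "P2"],
            "survival_5yr": ["deceased", "survivor"],
            "treatment": ["naive", "neoadjuvant"],
            "survival_months": [24.0, 80.0],
            "event_observed": [True, False],
        }
    )
    return Dataset(cells=cells, metadata=metadata, panel=toy_panel)


def random_core(
    rng: np.random.Generator,
    n: int,
    types: list[str] | None = None,
    core_id: str = "C",
    radius: float = 500.0,
) -> pd.DataFrame:
    """Uniform random cell table for geometry tests (no marker columns)."""
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "core_id": core_id,
            "x_um": r * np.cos(th),
            "y_um": r * np.sin(th),
            "area_um2": np.full(n, 100.0),
        }
    )
    if types is not None:
        df["cell_type"] = rng.choice(types, size=n)
    return df
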