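"""Synthetic TMA generator with planted ground truth.

Emulates a two-TMA metastatic-osteosarcoma-style study: 12 patients split
into a 5-year deceased cohort (8 patients, 18 cores) and a survivor cohort
(4 patients, 8 cores), each core a 2 mm disc (radius 1 000 um) holding
thousands of segmented cells. Every downstream stage's statistical
assumptions are built in:

* cells are scattered uniformly in the core disc with a hard-core minimum
  spacing (cells have bodies; keeps Delaunay graphs non-degenerate),
  except members of planted **niches** — circular regions with their own
  cell-type mixtures — which seed recoverable cellular neighborhoods;
* marker intensities follow cell-type **archetypes** (positive markers
  high, others low) derived from the shipped gating rules, with
  multiplicative log-normal noise (fluorescence is right-skewed);
* in survivor-cohort cores, immunosuppressive cells (Treg, TAM, MDSC) are
  displaced radially away from their nearest NK cell by a configurable
  factor (``proximity_effect``), planting a cohort difference in the
  spatial score while leaving tumor-NK distances untouched;
* a configurable fraction of cells carries QC-violating areas.

The generator uses a reduced 12-type phenotype alphabet by default (the
gating engine itself accepts the full rule set); all knobs live in
``SimConfig`` and everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ositme.io_model import Dataset, MarkerPanel, default_panel
from ositme.phenotyping import GatingRuleSet, default_gating_rules


class ConfigError(ValueError):
    pass


#: Default reduced phenotype alphabet: every type has a distinct signature
#: on the clustering-marker subset, and together the types cover every
#: clustering marker, so no clustering dimension is pure noise after
#: z-scoring (a pure-noise dimension would be inflated to unit variance and
#: could split clusters spuriously).
DEFAULT_TYPES = (
    "Epithelial",
    "Endothelial",
    "Lymphatic Endothelial",
    "Fibroblast",
    "Tumor",
    "Treg",
    "Helper T cell",
    "Cytotoxic T cell",
    "CD21+ B cell",
    "NK cell",
    "TAM",
    "MDSC",
    "Neutrophil",
)

IMMUNE_TYPES = frozenset(
    {
        "Treg",
        "Helper T cell",
        "Cytotoxic T cell",
        "CD21+ B cell",
        "NK cell",
        "TAM",
        "MDSC",
        "Neutrophil",
    }
)

#: Baseline core mixture: tumor/stroma dominated with a realistic immune
#: infiltrate; NK cells rare but present in every core.
DEFAULT_MIXTURE = {
    "Tumor": 0.30,
    "Epithelial": 0.12,
    "Endothelial": 0.06,
    "Lymphatic Endothelial": 0.03,
    "Fibroblast": 0.09,
    "MDSC": 0.10,
    "TAM": 0.07,
    "Neutrophil": 0.05,
    "Treg": 0.04,
    "Helper T cell": 0.05,
    "Cytotoxic T cell": 0.04,
    "CD21+ B cell": 0.02,
    "NK cell": 0.03,
}


@dataclass(frozen=True)
class NicheSpec:
    """A planted circular niche: its own type mixture inside a disc."""

    name: str
    radius_um: float
    fraction: float  # fraction of the core's cells belonging to the niche
    mixture: dict[str, float]


DEFAULT_NICHES = (
    NicheSpec(
        "tumor_core",
        radius_um=280.0,
        fraction=0.18,
        mixture={"Tumor": 0.85, "Fibroblast": 0.10, "MDSC": 0.05},
    ),
    NicheSpec(
        "immune_infiltrate",
        radius_um=220.0,
        fraction=0.12,
        mixture={
            "Helper T cell": 0.30,
            "Cytotoxic T cell": 0.25,
            "Treg": 0.10,
            "CD21+ B cell": 0.15,
            "NK cell": 0.10,
            "Endothelial": 0.10,
        },
    ),
    NicheSpec(
        "myeloid_suppressive",
        radius_um=220.0,
        fraction=0.12,
        mixture={"MDSC": 0.45, "TAM": 0.30, "Neutrophil": 0.15, "Tumor": 0.10},
    ),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-shape and noise parameters for the synthetic TMA.

    Defaults emulate the study shape: 8 deceased patients / 18 cores vs
    4 survivor patients / 8 cores, 2 mm cores, ~1e5 cells in total.
    """

    n_deceased_patients: int = 8
    n_survivor_patients: int = 4
    deceased_cores_total: int = 18
    survivor_cores_total: int = 8
    cells_per_core: tuple[int, int] = (2000, 6000)
    core_radius_um: float = 1000.0
    min_spacing_um: float = 5.0
    mixture_deceased: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    mixture_survivor: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    niches: tuple[NicheSpec, ...] = DEFAULT_NICHES
    proximity_effect: float = 2.0
    noise_sigma: float = 0.3
    qc_contamination: float = 0.02
    intensity_high: float = 40.0
    intensity_low: float = 8.0
    dapi_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (
            ("mixture_deceased", self.mixture_deceased),
            ("mixture_survivor", self.mixture_survivor),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-8:
                raise ConfigError(f"{name} must sum to 1")
        if self.proximity_effect < 1.0:
            raise ConfigError("proximity_effect must be >= 1")
        for n in (
            self.n_deceased_patients,
            self.n_survivor_patients,
            self.deceased_cores_total,
            self.survivor_cores_total,
        ):
            if n <= 0:
                raise ConfigError("patient/core counts must be positive")
        if self.cells_per_core[0] <= 0 or (
            self.cells_per_core[1] < self.cells_per_core[0]
        ):
            raise ConfigError("invalid cells_per_core range")
        frac = sum(n.fraction for n in self.niches)
        if frac > 1.0 + 1e-9:
            raise ConfigError("niche fractions exceed 1")
        for niche in self.niches:
            if niche.radius_um > self.core_radius_um:
                raise ConfigError(
                    f"niche {niche.name!r} radius exceeds core radius"
                )
            if abs(sum(niche.mixture.values()) - 1.0) > 1e-8:
                raise ConfigError(f"niche {niche.name!r} mixture must sum to 1")
        if not 0.0 <= self.qc_contamination < 1.0:
            raise ConfigError("qc_contamination must be in [0, 1)")


def study_shape_config(**overrides) -> SimConfig:
    """The default study-shaped configuration (12 patients, 26 cores)."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


@dataclass(frozen=True)
class ArchetypeMatrix:
    """Expected raw intensity per (cell type, marker), plus noise scale."""

    table: pd.DataFrame  # rows = types, columns = markers
    noise_sigma: float

    def mean_vector(self, cell_type: str) -> np.ndarray:
        return self.table.loc[cell_type].to_numpy(float)


def make_archetypes(
    types: tuple[str, ...],
    rules: GatingRuleSet,
    panel: MarkerPanel,
    high: float = 40.0,
    low: float = 8.0,
    dapi_mean: float = 50.0,
    noise_sigma: float = 0.3,
) -> ArchetypeMatrix:
    """Derive archetype intensity means from the gating rules.

    A type's positive markers (first matching rule) get the high mean,
    everything else the low mean; immune types additionally express CD45;
    the DAPI channel is high for every cell.
    """
    tbl = pd.DataFrame(low, index=list(types), columns=list(panel.markers))
    # union of positives across rules sharing a label (e.g. Fibroblasts
    # express both Collagen IV and SMA)
    by_label: dict[str, set[str]] = {}
    for r in rules.rules:
        by_label.setdefault(r.cell_type, set()).update(r.positive)
    for t in types:
        if t not in by_label:
            raise ConfigError(f"no gating rule for simulated type {t!r}")
        for m in by_label[t]:
            if m in tbl.columns:
                tbl.loc[t, m] = high
        if t in IMMUNE_TYPES and "CD45" in tbl.columns:
            tbl.loc[t, "CD45"] = high
    if "DAPI" in tbl.columns:
        tbl["DAPI"] = dapi_mean
    return ArchetypeMatrix(table=tbl, noise_sigma=noise_sigma)


@dataclass
class SyntheticTruth:
    """Planted ground truth aligned with the generated cells."""

    cells: pd.DataFrame  # cell_id, core_id, true_type, true_niche, niche_name
    core_cohort: dict[str, str]  # core_id -> {"deceased", "survivor"}
    archetypes: ArchetypeMatrix


@dataclass(frozen=True)
class CoreSpec:
    core_id: str
    patient_id: str
    cohort: str  # "deceased" | "survivor"
    treatment: str  # "naive" | "neoadjuvant"


def _sample_in_disc(rng: np.random.Generator, n: int, center, radius) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack(
        (center[0] + r * np.cos(theta), center[1] + r * np.sin(theta))
    )


class _SpacingGrid:
    """Hash-grid rejection sampler enforcing a hard-core minimum spacing."""

    def __init__(self, spacing: float) -> None:
        self.s = spacing
        self.s2 = spacing * spacing
        self.cells: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def try_add(self, x: float, y: float) -> bool:
        s = self.s
        ci, cj = int(x // s), int(y // s)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for px, py in self.cells.get((ci + di, cj + dj), ()):
                    dx, dy = x - px, y - py
                    if dx * dx + dy * dy < self.s2:
                        return False
        self.cells.setdefault((ci, cj), []).append((x, y))
        return True


def _place_points(
    rng: np.random.Generator,
    grid: _SpacingGrid,
    n: int,
    center,
    radius: float,
) -> np.ndarray:
    """Dart-throw n points uniformly in a disc subject to the spacing grid."""
    out = np.empty((n, 2))
    got = 0
    attempts = 0
    while got < n:
        batch = _sample_in_disc(rng, max(4 * (n - got), 64), center, radius)
        for x, y in batch:
            if grid.try_add(x, y):
                out[got] = (x, y)
                got += 1
                if got == n:
                    break
        attempts += 1
        if attempts > 200:
            raise ConfigError(
                "cannot place points at requested density and spacing"
            )
    return out


def _sample_niche_centers(
    rng: np.random.Generator, cfg: SimConfig
) -> list[np.ndarray]:
    centers: list[np.ndarray] = []
    for niche in cfg.niches:
        max_r = cfg.core_radius_um - niche.radius_um
        for _ in range(200):
            c = _sample_in_disc(rng, 1, (0.0, 0.0), max(max_r, 0.0))[0]
            ok = True
            for prev, spec in zip(centers, cfg.niches):
                if np.hypot(*(c - prev)) < niche.radius_um + spec.radius_um:
                    ok = False
                    break
            if ok:
                break
        centers.append(c)  # fall back to the last draw if crowded
    return centers


def _draw_types(
    rng: np.random.Generator, mixture: dict[str, float], n: int
) -> np.ndarray:
    names = list(mixture.keys())
    probs = np.array([mixture[t] for t in names], dtype=float)
    probs = probs / probs.sum()
    return np.array(names)[rng.choice(len(names), size=n, p=probs)]


def _displace_from_nk(
    sup: np.ndarray, nk: np.ndarray, effect: float, radius: float
) -> np.ndarray:
    """Push suppressor cells radially away from NK cells.

    The planted effect is on the *nearest*-NK distance: each suppressor's
    target distance is ``effect`` times its original nearest-NK distance.
    Because moving away from one NK can land a cell near another, the push
    is iterated (in polar coordinates about the current nearest NK) until
    the nearest-NK distance reaches the target or the core boundary caps
    it. ``effect == 1`` is the identity.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(nk)
    d0, _ = tree.query(sup, k=1)
    target = d0 * effect
    pos = sup.copy()
    for _ in range(12):
        d, j = tree.query(pos, k=1)
        short = d < target * 0.999
        if not short.any():
            break
        anchor = nk[j[short]]
        vec = pos[short] - anchor
        norm = np.linalg.norm(vec, axis=1)
        # coincident with an NK cell: pick a fixed direction
        degenerate = norm < 1e-9
        if degenerate.any():
            vec[degenerate] = (1.0, 0.0)
            norm[degenerate] = 1.0
        pos[short] = anchor + vec / norm[:, None] * target[short][:, None]
        r = np.linalg.norm(pos, axis=1)
        over = r > radius
        if over.any():
            pos[over] *= (radius / r[over])[:, None] * 0.999
    return pos


def simulate_core(
    cfg: SimConfig,
    core_spec: CoreSpec,
    seed: int | np.random.SeedSequence,
    panel: MarkerPanel,
    archetypes: ArchetypeMatrix,
    start_cell_id: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one core; returns (cell table, per-cell truth table).

    Survivor-cohort suppressor cells (Treg, TAM, MDSC) are re-placed at
    ``proximity_effect`` times their radial distance from the nearest NK
    cell (clipped to the core disc); everything else is untouched, so the
    planted effect moves only the suppressor->NK side of the score ratio.
    """
    rng = np.random.default_rng(seed)
    n_cells = int(rng.integers(cfg.cells_per_core[0], cfg.cells_per_core[1] + 1))
    mixture = (
        cfg.mixture_survivor
        if core_spec.cohort == "survivor"
        else cfg.mixture_deceased
    )

    grid = _SpacingGrid(cfg.min_spacing_um)
    niche_centers = _sample_niche_centers(rng, cfg)
    xs: list[np.ndarray] = []
    types: list[np.ndarray] = []
    niche_idx: list[np.ndarray] = []
    n_assigned = 0
    for i, niche in enumerate(cfg.niches):
        n_i = int(round(niche.fraction * n_cells))
        n_assigned += n_i
        pts = _place_points(rng, grid, n_i, niche_centers[i], niche.radius_um)
        xs.append(pts)
        types.append(_draw_types(rng, niche.mixture, n_i))
        niche_idx.append(np.full(n_i, i))
    n_bg = n_cells - n_assigned
    pts = _place_points(rng, grid, n_bg, (0.0, 0.0), cfg.core_radius_um)
    xs.append(pts)
    types.append(_draw_types(rng, mixture, n_bg))
    niche_idx.append(np.full(n_bg, -1))

    pos = np.vstack(xs)
    true_type = np.concatenate(types)
    true_niche = np.concatenate(niche_idx).astype(int)

    if core_spec.cohort == "survivor" and cfg.proximity_effect != 1.0:
        nk_mask = true_type == "NK cell"
        sup_mask = np.isin(true_type, ("Treg", "TAM", "MDSC"))
        if nk_mask.any() and sup_mask.any():
            pos[sup_mask] = _displace_from_nk(
                pos[sup_mask],
                pos[nk_mask],
                cfg.proximity_effect,
                cfg.core_radius_um,
            )

    means = archetypes.table.loc[true_type].to_numpy(float)
    noise = rng.lognormal(
        mean=-0.5 * archetypes.noise_sigma**2,
        sigma=archetypes.noise_sigma,
        size=means.shape,
    )
    intensity = means * noise

    area = np.exp(rng.normal(np.log(110.0), 0.30, size=n_cells))
    area = np.clip(area, 31.0, 399.0)
    if cfg.qc_contamination > 0:
        bad = rng.random(n_cells) < cfg.qc_contamination
        n_bad = int(bad.sum())
        if n_bad:
            big = rng.random(n_bad) < 0.5
            bad_area = np.where(
                big,
                rng.uniform(410.0, 800.0, n_bad),
                rng.uniform(2.0, 25.0, n_bad),
            )
            area[bad] = bad_area

    cell_ids = np.arange(start_cell_id, start_cell_id + n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "core_id": core_spec.core_id,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "area_um2": area,
        }
    )
    for j, m in enumerate(panel.markers):
        cells[m] = intensity[:, j]
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "core_id": core_spec.core_id,
            "true_type": true_type,
            "true_niche": true_niche,
            "niche_name": [
                cfg.niches[i].name if i >= 0 else "background"
                for i in true_niche
            ],
        }
    )
    return cells, truth


def _core_specs(cfg: SimConfig, rng: np.random.Generator) -> list[CoreSpec]:
    specs: list[CoreSpec] = []
    for cohort, n_pat, n_cores in (
        ("deceased", cfg.n_deceased_patients, cfg.deceased_cores_total),
        ("survivor", cfg.n_survivor_patients, cfg.survivor_cores_total),
    ):
        if n_cores < n_pat:
            raise ConfigError(f"{cohort}: fewer cores than patients")
        per = [n_cores // n_pat] * n_pat
        for i in range(n_cores % n_pat):
            per[i] += 1
        for p in range(n_pat):
            pid = f"P{cohort[0].upper()}{p + 1:02d}"
            treatment = "neoadjuvant" if rng.random() < 0.5 else "naive"
            for c in range(per[p]):
                specs.append(
                    CoreSpec(
                        core_id=f"{pid}_core{c + 1}",
                        patient_id=pid,
                        cohort=cohort,
                        treatment=treatment,
                    )
                )
    return specs


def simulate_dataset(
    cfg: SimConfig,
    panel: MarkerPanel | None = None,
    rules: GatingRuleSet | None = None,
    types: tuple[str, ...] = DEFAULT_TYPES,
) -> tuple[Dataset, SyntheticTruth]:
    """Generate a full study-shaped dataset plus its planted truth.

    Deceased patients receive an observed event within 60 months; survivor
    patients are censored beyond 60 months. Reproducible: the same config
    (including its seed) yields byte-identical output.
    """
    panel = panel or default_panel()
    rules = rules or default_gating_rules()
    archetypes = make_archetypes(
        types,
        rules,
        panel,
        high=cfg.intensity_high,
        low=cfg.intensity_low,
        dapi_mean=cfg.dapi_mean,
        noise_sigma=cfg.noise_sigma,
    )
    root = np.random.SeedSequence(cfg.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    specs = _core_specs(cfg, meta_rng)
    core_seeds = root.spawn(len(specs) + 1)[1:]

    all_cells: list[pd.DataFrame] = []
    all_truth: list[pd.DataFrame] = []
    next_id = 0
    for spec, ss in zip(specs, core_seeds):
        cells, truth = simulate_core(
            cfg, spec, ss, panel, archetypes, start_cell_id=next_id
        )
        next_id += len(cells)
        all_cells.append(cells)
        all_truth.append(truth)

    cells = pd.concat(all_cells, ignore_index=True)
    truth_cells = pd.concat(all_truth, ignore_index=True)

    meta_rows = []
    survival: dict[str, tuple[float, bool]] = {}
    for spec in specs:
        if spec.patient_id not in survival:
            if spec.cohort == "deceased":
                survival[spec.patient_id] = (
                    float(np.round(meta_rng.uniform(6.0, 54.0), 1)),
                    True,
                )
            else:
                survival[spec.patient_id] = (
                    float(np.round(meta_rng.uniform(61.0, 140.0), 1)),
                    False,
                )
        months, event = survival[spec.patient_id]
        meta_rows.append(
            {
                "core_id": spec.core_id,
                "patient_id": spec.patient_id,
                "survival_5yr": spec.cohort,
                "treatment": spec.treatment,
                "survival_months": months,
                "event_observed": event,
            }
        )
    metadata = pd.DataFrame(meta_rows)
    ds = Dataset(cells=cells, metadata=metadata, panel=panel)
    truth = SyntheticTruth(
        cells=truth_cells,
        core_cohort={s.core_id: s.cohort for s in specs},
        archetypes=archetypes,
    )
    return ds, truth
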