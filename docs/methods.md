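# Methods

`ositme` implements the downstream analysis of spatial multiplexed
immunofluorescence (CODEX/PhenoCycler-class) tissue-microarray studies of
the immune tumor microenvironment, together with a synthetic data
generator that plants recoverable ground truth. This note records the
models, the defaults and why they were chosen, and what the synthetic
benchmark does and does not demonstrate.

## Input model

The pipeline consumes segmented single-cell tables: one row per cell with
core identifier, centroid (µm, per-core origin, y down), area (µm²) and
mean intensity per marker, plus a core metadata table (patient, 5-year
survival cohort, treatment exposure, survival months, event indicator).
Image processing and segmentation are upstream and out of scope; the only
segmentation-derived rule retained is the 400 µm² cell-area threshold.

The default panel has 30 channels: DAPI plus 29 protein markers. The
canonical clustering set contains 19 lineage markers (CD11b, CD14, CD19,
CD20, CD21, CD31, CD3e, CD4, CD45, CD57, CD68, CD8, Collagen IV,
E-Cadherin, FOXP3, Pan-cytokeratin, Podoplanin, SMA, Vimentin); the
default panel omits CD19 (along with CD11c, CD163 and LAG-3, the markers
such panels typically drop for staining artifacts), so its effective
clustering set is the 18-marker intersection. Marker-panel construction
validates that the clustering set is a subset of the panel.

## Quality control

Four per-cell metrics: area; DNA signal (mean DAPI intensity); signal sum
(total intensity across all channels); and the coefficient of variation of
the per-cell intensity vector, using the population (n-denominator)
standard deviation since the channels of one cell are the whole population
of interest, with CV defined as 0 for an all-zero vector.

The metrics are standard for this assay class; the cutoffs are this
package's own defaults, all config-overridable: area ∈ [30, 400] µm²,
DNA signal at or above the per-core 1st percentile, signal sum within the
per-core [1st, 99th] percentiles, CV ≤ 2. Percentile rules are evaluated
per core because staining intensity drifts between cores. Percentiles use
order-statistic methods ("lower"/"higher"), so cutoffs are attained data
values and small cores are not over-trimmed. `resolve_thresholds` freezes
the percentile rules into absolute per-core cutoffs; filtering with
resolved thresholds is exactly idempotent (re-estimating percentiles on an
already-filtered table would otherwise trim another nominal tail each
pass). Note the percentile rules trim roughly their nominal fraction even
of perfectly clean data; that is inherent to percentile QC.

## Phenotyping

Normalization: per marker, `arcsinh(x / 5)` followed by a population
z-score, clipped to ±3; constant markers map to zero. The arcsinh
cofactor 5 and clipped z-score are the de-facto convention for
fluorescence-intensity cytometry-style data; the transform is monotone
per marker inside the clip range.

Clustering: Leiden community detection (resolution 1) on a 30-nearest-
neighbor graph built in clustering-marker space, seeded and deterministic.
Subclustering refines one parent cluster on a restricted parameter grid
(neighbors ∈ {50, 30, 10}, resolution ∈ {0.5, 0.1}); the grid restriction
is enforced unless explicitly overridden. UMAP parameters (min_dist
1e-4) are diagnostic only; no quantitative output depends on the
embedding.

Annotation: ordered gating rules on cluster-mean normalized expression
over the **full** panel (functional markers like HLA-DR, PD-1, IDO1 gate
clusters even though they do not drive clustering). A rule fires when all
its required-positive markers exceed and all required-negative markers
fall below the positivity threshold (0.5 z-units, the package's choice —
expert annotation is not reproducible in code); first match wins,
otherwise "Undefined". Rules are ordered structural → lymphoid → myeloid
→ marker-only → Tumor, so Vimentin positivity is the fallback mesenchymal
call; specific rules (e.g. PD-1⁺ Memory Helper T) precede their general
parents, which keeps the rule set shadow-free: the noiseless archetype of
every rule gates back to its own label (tested).

## Cell–cell interactions

Per core: Delaunay triangulation of the centroids of cells with area
≤ 400 µm²; triangles whose minimum internal angle is below 45° are
discarded before taking the edge union. The angle filter removes sliver
triangles that fabricate long-range "contacts" along the core boundary.
The filter is read as a triangle-angle rule (the natural reading for a
triangulation; a Voronoi-vertex-angle reading exists but is not
implemented), and both thresholds are configurable. The interaction
frequency of an unordered type pair is the number of retained edges
joining the two types divided by all retained edges in the core;
same-type edges count, and frequencies sum to 1 per core. No spatial
permutation null is computed — enrichment is assessed across cohorts, not
against a random-placement null.

Degenerate inputs: fewer than three usable cells, or collinear cells,
yield an empty graph with a warning. Cocircular four-point degeneracies
are not specially handled; continuous coordinates make them measure-zero,
and qhull's triangulation of a fixed input is deterministic.

## Cellular neighborhoods

Each annotated cell's window is itself plus its k = 10 nearest neighbors
(Euclidean, within the core); the window composition over cell types
(counts / 11) is pooled across cores and clustered by k-means
(k-means++, 10 restarts, fixed seed) into 12 neighborhoods by default.
The window includes the index cell, following the established CN
literature — a cell's own type is part of its milieu — and compositions
are unweighted by distance; both are switchable conventions. Distance
ties in neighbor selection have measure zero for continuous coordinates.

The CN profile heatmap scaling: row-normalize centroids to proportions,
divide each column by the global type abundance, apply log2 with
pseudocount ε = 1e-3 (keeps empty compositions finite without distorting
large entries). A neighborhood whose composition equals the global
mixture maps to a ~0 row. CN display names are user annotations, not
computed.

## Spatial score

For source type S and target type T in one core, every S cell contributes
its distance to the nearest T cell (excluding itself when S = T); the
summary is the median over source cells. This directed nearest-neighbor
reading of "median neighbor distance" is the package's choice;
mean-over-all-pairs is dominated by core geometry and is rejected as the
default (available behind a switch).

The per-core score for suppressor S ∈ {Treg, TAM, MDSC} is
`median(d(S→NK)) / median(d(Tumor→NK))`, and the composite score is the
arithmetic mean of the defined components. Larger scores mean
suppressors sit relatively far from NK cells while NK cells sit close to
tumor — a geometric proxy for freer effector activity, not a measurement
of effector function. Components with a missing population or zero
denominator are flagged undefined and dropped from the mean (never
imputed); a core with no defined component yields no score. The score is
invariant to coordinate scaling and rigid motions.

## Cohort statistics and survival

Welch's unequal-variance t-test compares per-core features between
cohorts, treating each core as an independent observation. This is the
exploratory-TMA convention and a known limitation (patients contribute
several cores); a patient-level aggregation mode exists but is not the
default, and no mixed models are fitted. Volcano tables report
log2 fold change with pseudocount ε = 1e-6 (on proportion-scale
features), the Welch statistic and Welch–Satterthwaite df, raw two-sided
p and −log10 p; a Benjamini–Hochberg q column is emitted for information
only — the significance convention is raw p < 0.05.

Survival: per-patient values are the mean over the patient's cores;
patients at or below the cohort median go LOW, above go HIGH (ties to
LOW — a deterministic rule the convention leaves open); groups are
compared by the log-rank (Mantel–Cox) test with right-censoring
(lifelines). The test statistic is validated against an explicit
hand-tabulated risk-set computation.

## Synthetic TMA generator

The generator emulates the study shape: 8 deceased-cohort patients with
18 cores and 4 survivor patients with 8 cores (cores split as evenly as
possible among a cohort's patients), 2 mm cores (radius 1 000 µm).
Deceased patients receive an observed event uniform in (6, 54) months;
survivors are censored beyond 60 months.

* **Geometry** — cells uniform in the core disc with a 5 µm hard-core
  minimum spacing (dart throwing on a hash grid); cells have bodies, and
  the spacing keeps Delaunay graphs non-degenerate. Planted niches are
  discs with their own type mixtures (defaults: a tumor core, a lymphoid
  infiltrate, a myeloid-suppressive niche; fractions 0.18/0.12/0.12).
* **Phenotypes** — a reduced 13-type alphabet (tumor, epithelial,
  endothelial, lymphatic endothelial, fibroblast, Treg, helper and
  cytotoxic T, B, NK, TAM, MDSC, neutrophil). Every clustering marker has
  a positive population: a marker expressed by no cell type would be
  z-scored into a unit-variance pure-noise dimension that can split
  clusters spuriously and push a spurious cluster mean past the gating
  threshold. The gating engine itself accepts the full shipped rule set.
* **Intensities** — archetype means derived from the gating rules
  (positives 40 AU, background 8 AU, DAPI 50 AU; immune types also
  express CD45) with multiplicative log-normal noise, σ = 0.3
  (fluorescence is right-skewed). The nonzero background keeps per-cell
  intensity CVs in the range real cells show (a near-zero background
  would make every cell's CV an artifact-level outlier).
* **Planted cohort effect** — in survivor cores, each Treg/TAM/MDSC cell
  is pushed radially away from NK cells until its nearest-NK distance is
  `proximity_effect` (default 2) times its original value, iterating
  because a single push can land a cell near a different NK cell; the
  push is capped at the core boundary. Tumor and NK positions are
  untouched, so only the numerator of the score ratio moves. With
  `proximity_effect = 1` the transform is the identity and the cohorts
  are exchangeable, which calibrates the type-I error of the whole
  score-plus-Welch pipeline.
* **QC contamination** — a configurable fraction of cells (default 2%)
  receives an out-of-range area; with the knob at 0 every generated cell
  satisfies the absolute QC rules (percentile rules still trim their
  nominal tail, see above).

Default core sizes are 2 000–6 000 cells (≈10⁵ cells per study). Tests
and the acceptance script run the same design at reduced per-core counts
(200–1 100 cells) chosen so Monte-Carlo replication and repeated
end-to-end runs stay desk-scale; the planted-effect detection and
calibration results quoted are computed at those sizes.

### What the benchmark does not show

The generator plants exactly the structure the pipeline looks for:
archetypal marker profiles with independent log-normal noise, circular
niches, and a radial proximity effect. Real tissue has correlated marker
noise, segmentation spillover, irregular niche geometry, staining
gradients and multi-nucleated-cell artifacts, none of which are
simulated. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure — not that the
pipeline's biological conclusions transfer to any particular real TMA.

## Numerical and design notes

* `cell_id` is the deterministic tie-breaker wherever order matters;
  all stochastic steps (Leiden, k-means, simulation) take explicit seeds,
  and the pipeline writes byte-identical outputs on re-run.
* Leiden cluster labels are relabeled to contiguous integers by first
  occurrence; k-means uses 10 restarts.
* CSV is the interchange format (comma, UTF-8, header, documented column
  order); `write_dataset`/`read_dataset` round-trip exactly.
* Known limitations: no image/segmentation I/O; no spatial-null
  interaction enrichment; no mixed-effects survival or abundance models;
  CN names are not computed; UMAP outputs are diagnostic only.
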