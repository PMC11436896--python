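import numpy as np
import pandas as pd
import pytest

from ositme.io_model import MarkerPanel, default_panel
from ositme.phenotyping import (
    ClusteringParams,
    GatingRule,
    GatingRuleSet,
    NormalizationParams,
    SubclusterParams,
    annotate_clusters,
    cell_type_proportions,
    cluster_cells,
    default_gating_rules,
    normalize_expression,
    subcluster,
)


def _frame(panel, values):
    df = pd.DataFrame(values, columns=list(panel.markers))
    return df


class TestNormalization:
    def test_constant_marker_maps_to_zero(self, toy_panel):
        cells = _frame(toy_panel, [[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        z = normalize_expression(cells, toy_panel)
        assert (z["M1"] == 0).all()

    def test_two_point_zscore(self, toy_panel):
        cells = _frame(toy_panel, [[0.0, 0.0], [7.0, 7.0]])
        z = normalize_expression(cells, toy_panel)
        # population SD of two points -> z-scores are exactly -1, +1
        assert z["M1"].tolist() == pytest.approx([-1.0, 1.0])

    def test_clip_boundary(self, toy_panel):
        vals = [[1.0, 0.0]] * 100 + [[1e9, 0.0]]
        z = normalize_expression(_frame(toy_panel, vals), toy_panel)
        assert z["M1"].max() == pytest.approx(3.0)

    def test_monotone_within_clip(self, toy_panel):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(2, 1, size=(200, 2))
        cells = _frame(toy_panel, vals)
        z = normalize_expression(cells, toy_panel)
        order_raw = np.argsort(vals[:, 0], kind="stable")
        z_sorted = z["M1"].to_numpy()[order_raw]
        assert (np.diff(z_sorted) >= -1e-12).all()

    def test_empty_input(self, toy_panel):
        z = normalize_expression(_frame(toy_panel, []), toy_panel)
        assert z.empty

    def test_invalid_cofactor(self):
        with pytest.raises(ValueError):
            NormalizationParams(arcsinh_cofactor=0)


def _two_blob_frame(panel, n=120, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.3, size=(n, 2))
    b = rng.normal(sep, 0.3, size=(n, 2))
    truth = np.repeat([0, 1], n)
    return _frame(panel, np.vstack([a, b])), truth


class TestClustering:
    def test_two_separated_blobs(self, toy_panel):
        from sklearn.metrics import adjusted_rand_score

        cells, truth = _two_blob_frame(toy_panel)
        z = normalize_expression(cells, toy_panel)
        # coarse resolution: the question is blob recovery, not substructure
        labels = cluster_cells(
            z, toy_panel, ClusteringParams(graph_neighbors=15, resolution=0.1)
        )
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_cells_one_cluster(self, toy_panel):
        cells = _frame(toy_panel, [[1.0, 1.0]] * 60)
        z = normalize_expression(cells, toy_panel)
        labels = cluster_cells(z, toy_panel, ClusteringParams(graph_neighbors=10))
        assert len(set(labels)) == 1

    def test_fixed_seed_deterministic(self, toy_panel):
        cells, _ = _two_blob_frame(toy_panel, seed=3)
        z = normalize_expression(cells, toy_panel)
        p = ClusteringParams(graph_neighbors=15, seed=42)
        l1 = cluster_cells(z, toy_panel, p)
        l2 = cluster_cells(z, toy_panel, p)
        assert (l1 == l2).all()

    def test_too_few_cells_raises(self, toy_panel):
        cells = _frame(toy_panel, [[1.0, 1.0]] * 5)
        z = normalize_expression(cells, toy_panel)
        with pytest.raises(ValueError, match="graph_neighbors"):
            cluster_cells(z, toy_panel, ClusteringParams(graph_neighbors=30))


class TestSubcluster:
    def test_grid_enforced(self):
        with pytest.raises(ValueError, match="neighbors"):
            SubclusterParams(graph_neighbors=17)
        with pytest.raises(ValueError, match="resolution"):
            SubclusterParams(resolution=0.7)
        SubclusterParams(graph_neighbors=17, resolution=0.7, allow_off_grid=True)

    def test_two_planted_states_recovered(self, toy_panel):
        from sklearn.metrics import adjusted_rand_score

        cells, truth = _two_blob_frame(toy_panel, n=80, seed=5)
        z = normalize_expression(cells, toy_panel)
        labels = subcluster(z, ["M1", "M2"], SubclusterParams(graph_neighbors=10))
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_homogeneous_parent_single_subcluster(self, toy_panel):
        rng = np.random.default_rng(1)
        cells = _frame(toy_panel, rng.normal(0, 0.1, size=(100, 2)))
        z = normalize_expression(cells, toy_panel)
        labels = subcluster(
            z, ["M1", "M2"], SubclusterParams(graph_neighbors=30, resolution=0.1)
        )
        assert len(set(labels)) == 1

    def test_labels_partition_parent(self, toy_panel):
        cells, _ = _two_blob_frame(toy_panel, n=50, seed=7)
        z = normalize_expression(cells, toy_panel)
        labels = subcluster(z, ["M1", "M2"], SubclusterParams(graph_neighbors=10))
        assert len(labels) == len(cells)
        assert set(labels) == set(range(len(set(labels))))


class TestGating:
    def _profile(self, panel, positives, level=2.0, base=-0.5):
        s = pd.Series(base, index=list(panel.markers))
        for m in positives:
            s[m] = level
        return s

    def test_mdsc_profile(self):
        panel = default_panel()
        rules = default_gating_rules()
        prof = self._profile(panel, ["CD14", "CD45"])
        means = pd.DataFrame([prof])
        assert annotate_clusters(means, rules)[0] == "MDSC"

    def test_tam_profile(self):
        panel = default_panel()
        rules = default_gating_rules()
        means = pd.DataFrame([self._profile(panel, ["CD68", "CD45"])])
        assert annotate_clusters(means, rules)[0] == "TAM"

    def test_macrophage_needs_hladr(self):
        panel = default_panel()
        rules = default_gating_rules()
        means = pd.DataFrame([self._profile(panel, ["CD68", "HLA-DR"])])
        assert annotate_clusters(means, rules)[0] == "Macrophage"

    def test_flat_profile_is_undefined(self):
        panel = default_panel()
        rules = default_gating_rules()
        means = pd.DataFrame([pd.Series(0.0, index=list(panel.markers))])
        assert annotate_clusters(means, rules)[0] == "Undefined"

    def test_vimentin_fallback_is_tumor(self):
        panel = default_panel()
        rules = default_gating_rules()
        means = pd.DataFrame([self._profile(panel, ["Vimentin"])])
        assert annotate_clusters(means, rules)[0] == "Tumor"

    def test_rule_markers_all_in_default_panel(self):
        default_gating_rules().validate_against(default_panel())

    def test_noiseless_archetypes_gate_bijectively(self):
        """Every rule's noiseless archetype profile maps back to its own
        label: the rule ordering has no shadowing."""
        panel = default_panel()
        rules = default_gating_rules()
        for rule in rules.rules:
            prof = self._profile(panel, rule.positive)
            assert rules.call(prof) == rule.cell_type, rule.cell_type


class TestProportions:
    def test_counting(self):
        cells = pd.DataFrame(
            {
                "core_id": ["A"] * 10,
                "cell_type": ["MDSC"] * 4 + ["Tumor"] * 6,
            }
        )
        p = cell_type_proportions(cells)
        assert p.loc["A", "MDSC"] == pytest.approx(0.4)

    def test_single_type_core(self):
        cells = pd.DataFrame({"core_id": ["A"] * 5, "cell_type": ["NK cell"] * 5})
        p = cell_type_proportions(cells)
        assert p.loc["A", "NK cell"] == 1.0

    def test_rows_sum_to_one(self, typed_cells):
        p = cell_type_proportions(typed_cells)
        assert np.allclose(p.sum(axis=1), 1.0)
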