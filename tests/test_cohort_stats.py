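import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import logrank_by_hand, welch_by_hand
from ositme.cohort_stats import (
    km_median_split,
    patient_means,
    volcano_table,
    welch_t_test,
)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_fixture_matches_hand_formula(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]
        t, df, p = welch_t_test(a, b)
        th, dfh, ph = welch_by_hand(a, b)
        assert t == pytest.approx(th, abs=1e-12)
        assert df == pytest.approx(dfh, abs=1e-12)
        assert p == pytest.approx(ph, abs=1e-12)
        assert t == pytest.approx(-1.7320508, abs=1e-6)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 5.0], [0.5, 3.0, 9.0, 2.0]
        t1, _, p1 = welch_t_test(a, b)
        t2, _, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_variance_unequal_means_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t_test([1.0, 1.0], [2.0, 2.0])

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t_test([1.0], [1.0, 2.0])


class TestVolcano:
    def _features(self, vals_a, vals_b, feature="f"):
        idx = [f"a{i}" for i in range(len(vals_a))] + [
            f"b{i}" for i in range(len(vals_b))
        ]
        feats = pd.DataFrame({feature: vals_a + vals_b}, index=idx)
        cohorts = pd.Series(
            ["A"] * len(vals_a) + ["B"] * len(vals_b), index=idx
        )
        return feats, cohorts

    def test_equal_means_zero_lfc(self):
        feats, cohorts = self._features([0.2, 0.3, 0.4], [0.4, 0.3, 0.2])
        out = volcano_table(feats, cohorts, "A", "B")
        assert out["lfc"].iloc[0] == pytest.approx(0.0)

    def test_lfc_formula(self):
        feats, cohorts = self._features([0.4, 0.4, 0.4001], [0.1, 0.1, 0.1001])
        out = volcano_table(feats, cohorts, "A", "B", eps=1e-6)
        expected = np.log2((feats.iloc[:3, 0].mean() + 1e-6) /
                           (feats.iloc[3:, 0].mean() + 1e-6))
        assert out["lfc"].iloc[0] == pytest.approx(expected)
        assert out["lfc"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_invariant_to_core_order(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(
            rng.random((10, 4)), columns=list("wxyz"),
            index=[f"c{i}" for i in range(10)],
        )
        cohorts = pd.Series(["A"] * 5 + ["B"] * 5, index=feats.index)
        out1 = volcano_table(feats, cohorts, "A", "B")
        perm = rng.permutation(10)
        out2 = volcano_table(feats.iloc[perm], cohorts, "A", "B")
        pd.testing.assert_frame_equal(out1, out2)

    def test_unassigned_core_raises(self):
        feats, cohorts = self._features([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match="without cohort"):
            volcano_table(feats, cohorts.iloc[:3], "A", "B")

    def test_null_calibration(self):
        """With no effect, ~5% of features reject at p < 0.05."""
        rng = np.random.default_rng(123)
        rejections, total = 0, 0
        for _ in range(200):
            feats = pd.DataFrame(
                rng.normal(size=(26, 10)),
                index=[f"c{i}" for i in range(26)],
            )
            cohorts = pd.Series(["A"] * 18 + ["B"] * 8, index=feats.index)
            out = volcano_table(feats, cohorts, "A", "B")
            rejections += (out["p_value"] < 0.05).sum()
            total += len(out)
        rate = rejections / total
        assert 0.03 <= rate <= 0.07

    def test_planted_interaction_ranks_first(self):
        """A cohort-specific MDSC excess makes an MDSC interaction pair the
        top-ranked interaction feature."""
        from dataclasses import replace
        from ositme.interactions import interaction_feature_table
        from ositme.synthetic import DEFAULT_MIXTURE, SimConfig, simulate_dataset

        mix_dec = dict(DEFAULT_MIXTURE)
        mix_dec["MDSC"] = 0.30
        mix_dec["Tumor"] = 0.10
        cfg = replace(
            SimConfig(),
            cells_per_core=(250, 350),
            mixture_deceased=mix_dec,
            proximity_effect=1.0,
            qc_contamination=0.0,
            seed=77,
        )
        ds, truth = simulate_dataset(cfg)
        cells = ds.cells.merge(
            truth.cells[["cell_id", "true_type"]], on="cell_id"
        ).rename(columns={"true_type": "cell_type"})
        feats = interaction_feature_table(cells)
        cohorts = ds.metadata.set_index("core_id")["survival_5yr"]
        out = volcano_table(feats, cohorts, "deceased", "survivor")
        top = out.sort_values("neg_log10_p", ascending=False).iloc[0]
        assert "MDSC" in top["feature"]


class TestKaplanMeier:
    def _meta(self, patients, months, events):
        return pd.DataFrame(
            {
                "core_id": [f"c{i}" for i in range(len(patients))],
                "patient_id": patients,
                "survival_months": months,
                "event_observed": events,
            }
        )

    def test_median_split_assignment(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("pqrs"))
        meta = self._meta(list("pqrs"), [10, 20, 30, 40], [True] * 4)
        meta["patient_id"] = list("pqrs")
        table, _, _ = km_median_split(vals, meta)
        assert set(table.loc[table["group"] == "LOW"].index) == {"p", "q"}
        assert set(table.loc[table["group"] == "HIGH"].index) == {"r", "s"}

    def test_identical_survival_experience(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("pqrs"))
        meta = self._meta(list("pqrs"), [10, 10, 10, 10], [True] * 4)
        _, chi2, p = km_median_split(vals, meta)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulated_mantel_cox(self):
        """10-patient fixture with censoring: lifelines' statistic equals
        an explicit risk-table computation."""
        patients = [f"P{i}" for i in range(10)]
        vals = pd.Series(
            [0.1, 0.2, 0.3, 0.4, 0.45, 0.6, 0.7, 0.8, 0.9, 1.0],
            index=patients,
        )
        months = [5.0, 8.0, 12.0, 20.0, 33.0, 40.0, 48.0, 60.0, 72.0, 80.0]
        events = [True, True, True, False, True, True, False, True, False, False]
        meta = self._meta(patients, months, events)
        table, chi2, p = km_median_split(vals, meta)
        group = (table["group"] == "HIGH").astype(int).to_numpy()
        expected_chi2 = logrank_by_hand(
            table["survival_months"], table["event_observed"], group
        )
        assert chi2 == pytest.approx(expected_chi2, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1), abs=1e-10)

    def test_scale_invariance(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("abcdef"))
        meta = self._meta(
            list("abcdef"), [9, 18, 27, 36, 45, 54], [True] * 6
        )
        t1, chi1, p1 = km_median_split(vals, meta)
        t2, chi2_, p2 = km_median_split(vals * 100.0, meta)
        assert (t1["group"] == t2["group"]).all()
        assert chi1 == pytest.approx(chi2_)

    def test_identical_values_raise(self):
        vals = pd.Series([1.0] * 4, index=list("pqrs"))
        meta = self._meta(list("pqrs"), [10, 20, 30, 40], [True] * 4)
        with pytest.raises(ValueError, match="identical"):
            km_median_split(vals, meta)

    def test_patient_means_average_cores(self):
        feats = pd.DataFrame({"f": [1.0, 3.0, 10.0]}, index=["c1", "c2", "c3"])
        meta = pd.DataFrame(
            {"core_id": ["c1", "c2", "c3"], "patient_id": ["p", "p", "q"]}
        )
        pm = patient_means(feats, meta, "f")
        assert pm["p"] == pytest.approx(2.0)
        assert pm["q"] == pytest.approx(10.0)
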