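"""Cohort comparison and survival statistics.

Any per-core feature table (cell-type proportions, interaction
frequencies, CN proportions, spatial scores) can be compared across two
cohorts with Welch's unequal-variance t-test, treating each core as an
independent observation — the convention of exploratory TMA analyses,
acknowledged as a limitation since patients contribute several cores. The
volcano substrate reports log2 fold change (with pseudocount), the Welch
statistic, Welch-Satterthwaite degrees of freedom, raw two-sided p, and a
Benjamini-Hochberg q-value for information only (no correction is applied
to the significance call, matching the raw-p volcano convention).

Survival: per-patient feature values (mean over the patient's cores) are
median-split into HIGH/LOW groups and compared with the log-rank
(Mantel-Cox) test under right-censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CohortComparison:
    feature: str
    mean_a: float
    mean_b: float
    lfc: float
    t: float
    welch_df: float
    p_value: float
    neg_log10_p: float


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    Degenerate inputs: if both groups have zero variance and equal means,
    (0, n_a + n_b - 2, 1) is returned; zero variance in only one
    configuration that makes the statistic undefined raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def volcano_table(
    features: pd.DataFrame,
    cohorts: pd.Series,
    group_a: str,
    group_b: str,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-feature Welch comparison of group_a vs group_b cores.

    ``features``: rows = core_id, columns = features. ``cohorts`` maps
    core_id -> cohort label; every core must belong to exactly one group.
    lfc = log2((mean_a + eps) / (mean_b + eps)); positive lfc means
    enrichment in group_a. Features with undefined statistics (e.g. zero
    variance in both groups with unequal means) are skipped with a
    warning column absent from the output. Output is sorted by feature
    name, so it is invariant to core ordering.
    """
    cohorts = cohorts.reindex(features.index)
    if cohorts.isna().any():
        missing = list(features.index[cohorts.isna()])
        raise ValueError(f"cores without cohort assignment: {missing}")
    in_a = cohorts == group_a
    in_b = cohorts == group_b
    rows = []
    for feat in sorted(features.columns):
        va = features.loc[in_a, feat].to_numpy(float)
        vb = features.loc[in_b, feat].to_numpy(float)
        va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
        try:
            t, df, p = welch_t_test(va, vb)
        except ValueError:
            continue
        ma, mb = va.mean(), vb.mean()
        rows.append(
            {
                "feature": feat,
                f"mean_{group_a}": ma,
                f"mean_{group_b}": mb,
                "lfc": float(np.log2((ma + eps) / (mb + eps))),
                "t": t,
                "welch_df": df,
                "p_value": p,
                "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["bh_q"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.reset_index(drop=True)


def patient_means(
    features: pd.DataFrame, metadata: pd.DataFrame, feature: str
) -> pd.Series:
    """Per-patient mean of a per-core feature over each patient's cores."""
    meta = metadata.set_index("core_id")
    vals = features[feature].dropna()
    patients = meta.loc[vals.index, "patient_id"]
    return vals.groupby(patients).mean()


def km_median_split(
    patient_values: pd.Series, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, float, float]:
    """Median-split survival analysis.

    ``patient_values``: per-patient feature values (index = patient_id).
    ``metadata`` supplies per-patient ``survival_months`` and
    ``event_observed`` (constant across a patient's cores). Patients at or
    below the median go to LOW, above to HIGH. Returns
    (assignment table, log-rank chi-square, p). Raises when the split is
    impossible (all values identical) or a group has < 2 patients.
    """
    med = float(patient_values.median())
    group = pd.Series(
        np.where(patient_values > med, "HIGH", "LOW"),
        index=patient_values.index,
        name="group",
    )
    if group.nunique() < 2:
        raise ValueError("median split impossible: all values identical")
    if (group == "HIGH").sum() < 2 or (group == "LOW").sum() < 2:
        raise ValueError("median split leaves a group with < 2 patients")

    surv = (
        metadata.groupby("patient_id")
        .agg(
            survival_months=("survival_months", "first"),
            event_observed=("event_observed", "first"),
        )
        .loc[patient_values.index]
    )
    from lifelines.statistics import logrank_test

    hi = group == "HIGH"
    res = logrank_test(
        surv.loc[hi, "survival_months"],
        surv.loc[~hi, "survival_months"],
        event_observed_A=surv.loc[hi, "event_observed"].astype(bool),
        event_observed_B=surv.loc[~hi, "event_observed"].astype(bool),
    )
    table = pd.DataFrame(
        {
            "value": patient_values,
            "group": group,
            "survival_months": surv["survival_months"],
            "event_observed": surv["event_observed"].astype(bool),
        }
    )
    table.index.name = "patient_id"
    return table, float(res.test_statistic), float(res.p_value)
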