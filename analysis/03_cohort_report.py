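#!/usr/bin/env python
"""Summarize the cohort findings of the pipeline run.

Reads the volcano tables and spatial-score outputs from results/run/ and
reports: phenotypes enriched by 5-year survival status, the top
differential cell-cell interactions, cellular-neighborhood enrichment,
and whether the composite spatial score separates the cohorts (it should:
the generator plants a survivor-cohort proximity effect). Writes
results/summary.json.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))


def top_rows(path: Path, k: int = 5) -> pd.DataFrame:
    vt = pd.read_csv(path)
    return vt.sort_values("p_value").head(k)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=REPO / "results" / "run")
    ap.add_argument("--out", type=Path,
                    default=REPO / "results" / "summary.json")
    args = ap.parse_args()

    summary = {}
    for label, fname in (
        ("cell_types", "volcano_cell_types.csv"),
        ("interactions", "volcano_interactions.csv"),
        ("neighborhoods", "volcano_cns.csv"),
        ("spatial_scores", "volcano_spatial_scores.csv"),
    ):
        top = top_rows(args.run / fname)
        print(f"\n== {label}: top features by Welch p (deceased vs survivor)")
        cols = ["feature", "lfc", "t", "p_value"]
        print(top[cols].to_string(index=False))
        summary[label] = top[cols].to_dict(orient="records")

    vt = pd.read_csv(args.run / "volcano_spatial_scores.csv")
    row = vt.loc[vt["feature"] == "os_spatial_score"].iloc[0]
    direction = (
        "higher in survivors"
        if row["mean_survivor"] > row["mean_deceased"]
        else "higher in deceased"
    )
    print(
        f"\ncomposite spatial score: deceased mean {row['mean_deceased']:.3f} "
        f"vs survivor mean {row['mean_survivor']:.3f} ({direction}), "
        f"Welch p = {row['p_value']:.4g}"
    )
    km = json.loads((args.run / "km_os_spatial_score.json").read_text())
    if "logrank_p" in km:
        print(
            f"median-split log-rank on the composite score: "
            f"chi2 = {km['logrank_chi2']:.3f}, p = {km['logrank_p']:.4g}"
        )
    summary["km_os_spatial_score"] = km

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(summary, indent=2))
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
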