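#!/usr/bin/env python
"""Group statistics: PAP differences across vowels and between groups, the
See->Sah delta analysis (mixed-design repeated-measures ANOVA), and the
feature-vs-PAP correlation table behind the heatmap.

Reads results/features.csv and results/cohort/pap.csv (run analyses 01 and
02 first); writes comparisons.csv, deltas.csv, correlation_matrix.csv.
"""

from pathlib import Path

import pandas as pd

from vowelpap.pipeline import comparison_tables

ROOT = Path(__file__).resolve().parent.parent


def main():
    results = ROOT / "results"
    features = pd.read_csv(results / "features.csv")
    pap = pd.read_csv(results / "cohort" / "pap.csv")

    comparisons, deltas, corr = comparison_tables(features, pap)
    comparisons.to_csv(results / "comparisons.csv", index=False)
    deltas.to_csv(results / "deltas.csv", index=False)
    corr.to_csv(results / "correlation_matrix.csv", index=False)

    by_group = deltas.groupby("group")["delta"].agg(["mean", "std"]).round(1)
    print("See - Sah PAP delta (mm):")
    print(by_group.to_string())
    inter = comparisons.set_index("comparison").loc[
        "pap_delta_group_x_vowel_interaction"]
    print(f"group x vowel interaction: F = {inter.statistic:.1f}, "
          f"p = {inter.p:.2g}")
    f2 = corr[(corr.feature == "F2") & (corr.vowel == "i")].iloc[0]
    print(f"F2 vs PAP during 'see': r = {f2.r:.2f}, p = {f2.p:.3f} "
          f"({f2.method})")
    sig = corr[(corr.p < 0.05)]
    print(f"{len(sig)} / {len(corr)} feature x vowel correlations "
          "significant at raw p < 0.05")


if __name__ == "__main__":
    main()
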