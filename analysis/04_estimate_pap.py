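#!/usr/bin/env python
"""Estimate PAP diameter from the 106 acoustic features with the two-step
stacked model: six-fold CV; linear, random-forest, neural-network and
1-D convolutional base regressors; random-forest combiner on the pooled
out-of-fold predictions.

Reads results/features.csv + results/cohort/pap.csv; writes estimation.csv
(per-sample out-of-fold predictions) and metrics.csv (fold-wise and overall
RMSE / r per model).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from vowelpap.estimator import stacked_cv
from vowelpap.features import FEATURE_NAMES

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=17)
    parser.add_argument("--mode", default="by_observation",
                        choices=["by_observation", "by_participant"])
    args = parser.parse_args()

    results = ROOT / "results"
    features = pd.read_csv(results / "features.csv")
    pap = pd.read_csv(results / "cohort" / "pap.csv")
    merged = features.merge(pap[["participant_id", "vowel", "pap_mm"]],
                            on=["participant_id", "vowel"])
    X = merged[list(FEATURE_NAMES)].to_numpy(float)
    y = merged["pap_mm"].to_numpy(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = stacked_cv(X, y, seed=args.seed, mode=args.mode,
                            groups=merged["participant_id"].to_numpy())

    estimation = merged[["participant_id", "vowel", "pap_mm"]].copy()
    for name, pred in result.predictions.items():
        estimation[f"pred_{name}"] = pred
    estimation["fold"] = result.fold_plan.assignment + 1
    estimation.to_csv(results / "estimation.csv", index=False)
    table = result.metrics_table()
    table.to_csv(results / "metrics.csv", index=False)

    print(f"{len(y)} samples, six-fold CV ({args.mode})")
    print(table.round(2).to_string(index=False))
    rmse, r = result.overall("stacked")
    print(f"stacked model: overall RMSE = {rmse:.2f} mm, r = {r:.2f}")


if __name__ == "__main__":
    main()
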