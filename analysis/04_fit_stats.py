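#!/usr/bin/env python
"""Fit the gravity-effect mixed models and apply Benjamini-Hochberg.

Averages the per-trial features within participant x condition, normalizes
EMG RMS per participant/muscle/phase by the maximum across conditions, fits
one participant-random-intercept LMM per dependent variable (gravity and
speed as categorical fixed effects), and adjusts the 26 gravity-effect
p-values with the Benjamini-Hochberg step-up procedure.

  python analysis/04_fit_stats.py --features results/features.tsv
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from gravgait.pipeline import condition_means
from gravgait.stats import run_table2


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path,
                    default=Path("results/features.tsv"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/stats_report.json"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    feats = pd.read_csv(args.features, sep="\t")
    feats = feats[feats["good"]]
    means = condition_means(feats)
    report = run_table2(means, alpha=args.alpha)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(report.to_jsonable(), fh, indent=2)

    tab = report.table
    n_sig = int(tab["significant"].sum())
    print(f"{report.family_size} gravity-effect tests, {n_sig} significant "
          f"after BH at alpha={args.alpha}; report in {args.out}")
    print(tab[["group", "variable", "p_raw", "p_adjusted",
               "significant"]].to_string(index=False,
                                         float_format=lambda v: f"{v:.4g}"))
    if report.missing:
        print(f"missing variables: {', '.join(report.missing)}")


if __name__ == "__main__":
    main()
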