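#!/usr/bin/env python
"""Detect gait events and classify trial validity for a cohort on disk.

For every trial bundle: find the right heel strikes (18 N vertical-force
threshold, delay-offset kinematic fallback beyond the plates), toe-off,
and the good-trial classification; write one events.json per bundle and a
cohort-wide summary table.

  python analysis/02_detect_events.py --cohort scratch/cohort \
      --out results/events_summary.tsv
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from gravgait.errors import GaitError
from gravgait.events import classify_trial, segment_stride
from gravgait.trial_io import read_trial


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/events_summary.tsv"))
    args = ap.parse_args()

    rows = []
    bundles = sorted(p for p in args.cohort.iterdir() if p.is_dir())
    for bundle in bundles:
        trial = read_trial(bundle)
        try:
            seg = segment_stride(trial)
            validity = classify_trial(trial, seg)
            record = {
                "rhs1": seg.rhs1, "rto": seg.rto, "rhs2": seg.rhs2,
                "source": seg.source, "good": validity.good,
                "reasons": validity.reasons,
            }
        except GaitError as exc:
            record = {"good": False, "reasons": [f"error: {exc}"]}
        with open(bundle / "events.json", "w") as fh:
            json.dump(record, fh, indent=2)
        rows.append({"bundle": bundle.name,
                     "participant": trial.meta.participant_id,
                     "gravity": trial.meta.gravity_level,
                     "speed": trial.meta.target_speed, **record,
                     "reasons": ";".join(record["reasons"])})
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    n_good = int(df["good"].sum())
    n_kin = int((df.get("source") == "kinematic_offset").sum())
    print(f"{len(df)} trials: {n_good} good, "
          f"{n_kin} used the delay-offset kinematic second heel strike; "
          f"summary in {args.out}")


if __name__ == "__main__":
    main()
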