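#!/usr/bin/env python
"""Simulate a demonstration cohort of reduced-gravity walking trials.

Generates synthetic trials across the gravity x speed grid and writes them
as TSV+JSON trial bundles plus a cohort ground-truth JSON.  Bundles are
bulky raw data, so they default into scratch/ rather than results/.

  python analysis/01_simulate_cohort.py --seed 1
  python analysis/01_simulate_cohort.py --participants 12 \
      --trials-per-condition 4 --out scratch/cohort_full
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from gravgait.synthetic import GeneratorConfig, GroundTruth, iter_cohort
from gravgait.trial_io import write_trial


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--participants", type=int, default=2)
    ap.add_argument("--gravities", type=float, nargs="+",
                    default=[1.0, 0.76, 0.55, 0.31])
    ap.add_argument("--speeds", type=float, nargs="+", default=[0.4, 1.2])
    ap.add_argument("--trials-per-condition", type=int, default=1)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/cohort"))
    args = ap.parse_args()

    cfg = GeneratorConfig(
        n_participants=args.participants,
        gravity_levels=tuple(args.gravities),
        speeds=tuple(args.speeds),
        trials_per_condition=args.trials_per_condition,
        seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    truths = []
    for i, (trial, truth) in enumerate(iter_cohort(cfg)):
        name = (f"{trial.meta.participant_id}_g{trial.meta.gravity_level:g}"
                f"_v{trial.meta.target_speed:g}_{i:04d}")
        write_trial(trial, args.out / name)
        truths.append({"bundle": name, **truth.to_jsonable()})
    with open(args.out / "truth.json", "w") as fh:
        json.dump({"config_seed": cfg.seed, "trials": truths}, fh, indent=2)
    print(f"wrote {len(truths)} trial bundles to {args.out} "
          f"({cfg.n_participants} participants, "
          f"{len(cfg.gravity_levels)} gravity levels, "
          f"{len(cfg.speeds)} speeds, truth in truth.json)")


if __name__ == "__main__":
    main()
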