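#!/usr/bin/env python
"""Tip morphometry and trajectory metrics across the simulated cohort.

Reads the SWC cohort from 01_simulate_cohort.py, computes per-nerve U-turn
rate (top-20 longest axons, >90° rule), branching index (tips per axon),
image-free tip ratios, and writes results/morphology/per_nerve.csv for the
group comparison.
"""

from pathlib import Path

import pandas as pd

import axonquant as aq
from axonquant import nerve_metrics as nm
from axonquant.errors import InsufficientLengthError

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = ROOT / "cohort"
OUT = ROOT / "morphology"


def main() -> None:
    if not COHORT.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for arm_dir in sorted(COHORT.iterdir()):
        for nerve_dir in sorted(arm_dir.iterdir()):
            trees = aq.read_swc(nerve_dir / "axons.swc")
            tm = nm.trajectory_metrics(trees, selection="top_20_longest")
            _, top5 = nm.axon_lengths(trees)
            bulbs = measured = 0
            for t in trees:
                try:
                    m = nm.measure_tip(t)
                except InsufficientLengthError:
                    continue
                measured += 1
                bulbs += m.klass == "retraction_bulb"
            rows.append({
                "arm": arm_dir.name,
                "nerve": nerve_dir.name,
                "n_axons": len(trees),
                "uturn_rate": tm.uturn_rate,
                "branching_index": tm.branching_index,
                "top5_mean_length_um": top5,
                "bulb_fraction": bulbs / measured if measured else float("nan"),
            })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "per_nerve.csv", index=False)
    summary = df.groupby("arm")[
        ["uturn_rate", "branching_index", "top5_mean_length_um",
         "bulb_fraction"]
    ].mean().round(3)
    print(summary.to_string())
    print(f"per-nerve morphology written to {OUT / 'per_nerve.csv'}")


if __name__ == "__main__":
    main()
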