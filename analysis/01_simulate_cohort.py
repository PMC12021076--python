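#!/usr/bin/env python
"""Simulate a two-arm cohort of regenerating nerves with ground truth.

Arm A mimics a weakly regenerating condition (short extensions, frequent
retraction bulbs, frequent U-turns); arm B a strongly regenerating one
(longer extensions, slim growth cones, fewer U-turns). Writes per-nerve
SWC trajectories, per-axon labels, and exact crossing tables under
results/cohort/.
"""

from pathlib import Path

import axonquant as aq

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

ARMS = {
    "armA": dict(length_scale=250.0, p_uturn=0.45, p_bulb=0.35,
                 branch_rate=0.3),
    "armB": dict(length_scale=450.0, p_uturn=0.15, p_bulb=0.08,
                 branch_rate=1.2),
}
N_NERVES = 3
BASE_SEED = 100


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for arm, params in ARMS.items():
        for k in range(N_NERVES):
            cfg = aq.NerveSimConfig(
                n_axons=12, seed=BASE_SEED + 1000 * (arm == "armB") + k,
                tortuosity_sd=6.0, step=8.0, nerve_length=1500.0,
                nerve_radius=120.0, **params,
            )
            gt = aq.simulate_nerve(cfg)
            d = OUT / arm / f"nerve{k:02d}"
            d.mkdir(parents=True, exist_ok=True)
            aq.write_swc(gt.axons, d / "axons.swc",
                         header=f"{arm} nerve {k}, seed {cfg.seed}")
            gt.labels.to_csv(d / "labels.csv", index=False)
            gt.crossing_table.to_csv(d / "crossing_table.csv", index=False)
        print(f"{arm}: {N_NERVES} nerves x 12 axons "
              f"(length_scale={params['length_scale']} um, "
              f"p_uturn={params['p_uturn']})")
    print(f"wrote ground-truth cohort under {OUT}")


if __name__ == "__main__":
    main()
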