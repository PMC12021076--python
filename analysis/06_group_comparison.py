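#!/usr/bin/env python
"""Statistical comparison of the cohort arms.

Reads per-nerve morphology metrics from 03_axon_morphology.py and compares
the arms with the two-tailed pooled-variance t test (significance read at
p < 0.05). Writes results/stats/comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from axonquant.stats import two_sample_t

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "stats"

METRICS = ["uturn_rate", "branching_index", "top5_mean_length_um",
           "bulb_fraction"]


def main() -> None:
    per_nerve = ROOT / "morphology" / "per_nerve.csv"
    if not per_nerve.exists():
        raise SystemExit("run 03_axon_morphology.py first")
    df = pd.read_csv(per_nerve)
    arms = sorted(df.arm.unique())
    rows = []
    for metric in METRICS:
        groups = [df[df.arm == a][metric].dropna().to_numpy() for a in arms]
        res = two_sample_t(groups[0], groups[1], labels=arms)
        rows.append({
            "metric": metric,
            "mean_" + arms[0]: groups[0].mean(),
            "mean_" + arms[1]: groups[1].mean(),
            "t": res.statistic, "df": res.df, "p": res.p_value,
            "significant": res.significant,
        })
    out = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    out.to_csv(OUT / "comparisons.csv", index=False)
    print(out.round(4).to_string(index=False))
    print(f"written to {OUT / 'comparisons.csv'}")


if __name__ == "__main__":
    main()
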