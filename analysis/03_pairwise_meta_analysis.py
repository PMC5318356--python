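#!/usr/bin/env python
"""Step one of the evidence synthesis: pairwise random-effects meta-analysis.

Pools every direct comparison per endpoint with DerSimonian-Laird
random-effects weights (mean differences for the two continuous
endpoints, odds ratios for the rest) and writes one table per endpoint.
Run analysis/02_simulate_trials.py first.
"""

import math
from pathlib import Path

import pandas as pd

from migranet import ENDPOINTS, pairwise_table, read_arm_table

OUT = Path(__file__).resolve().parents[1] / "results"
arms = read_arm_table(OUT / "arms.csv")

for code, ep in ENDPOINTS.items():
    rows = []
    for p in pairwise_table(arms, code):
        tr = math.exp if p.scale == "logOR" else (lambda v: v)
        rows.append(
            {
                "ref": p.comparison[0].name,
                "alt": p.comparison[1].name,
                "k": p.k,
                "effect": tr(p.pooled),
                "ci_low": tr(p.ci_low),
                "ci_high": tr(p.ci_high),
                "tau2": p.tau2,
                "Q": p.Q,
                "I2": p.I2,
                "scale": "OR" if p.scale == "logOR" else "MD",
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / f"pairwise_{ep.name}.csv", index=False, float_format="%.4g")
    sig = sum(
        1 for r in rows
        if (r["scale"] == "OR" and not r["ci_low"] <= 1 <= r["ci_high"])
        or (r["scale"] == "MD" and not r["ci_low"] <= 0 <= r["ci_high"])
    )
    print(f"{ep.name:<24} {len(rows)} comparisons, {sig} significant")

print(f"\nwrote pairwise_<endpoint>.csv under {OUT}")
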