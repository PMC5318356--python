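#!/usr/bin/env python
"""Comparison-adjusted funnel data and Egger asymmetry tests per endpoint.

Study effects are centered on their own comparison's pooled estimate so
all comparisons share one funnel; Egger's regression of the standardized
centered effect on precision quantifies small-study asymmetry.
"""

from pathlib import Path

import pandas as pd

from migranet import ENDPOINTS, build_network, funnel_data, pairwise_table, read_arm_table
from migranet.pairwise import study_effects

OUT = Path(__file__).resolve().parents[1] / "results"
arms = read_arm_table(OUT / "arms.csv")

for code, ep in ENDPOINTS.items():
    net = build_network(arms, code)
    effects = study_effects(net)
    pooled = pairwise_table(arms, code)
    data, egger = funnel_data(effects, pooled)
    pd.DataFrame(
        [
            {
                "study_id": d.study_id,
                "ref": d.comparison[0].name,
                "alt": d.comparison[1].name,
                "centered_effect": d.centered_effect,
                "se": d.se,
            }
            for d in data
        ]
    ).to_csv(OUT / f"funnel_{ep.name}.csv", index=False, float_format="%.4g")
    if egger:
        print(
            f"{ep.name:<24} {len(data):>2} studies, Egger intercept "
            f"{egger['intercept']:+.3f} (p = {egger['p']:.3f})"
        )
    else:
        print(f"{ep.name:<24} {len(data):>2} studies, too few for Egger")

print(f"\nwrote funnel_<endpoint>.csv under {OUT}")
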