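"""Evaluate utilization scores through ad show-conversion metrics.

Labels conversions (a facility visit within 14 days of that facility's
impression, with no visit in the prior 30 days), smooths them into the
local show-conversion-rate curve, maps scores to bid coefficients, and
compares two A/B arms.
"""

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

import geoseek as gs

rng = np.random.default_rng(0)
world = gs.generate_world(gs.WorldConfig(seed=7))
n = 4000
truth = pd.DataFrame({
    "user_id": [f"U{i:05d}" for i in range(n)],
    "label": ["control"] * n,
    "latent_risk": rng.uniform(0, 1, n),
    "first_visit_time": [None] * n,
    "visit_type": [None] * n,
})
impressions, visits = gs.generate_ad_stream(
    truth, world.facilities,
    gs.AdStreamConfig(base_conversion_rate=0.02, risk_slope=0.4, seed=1))
converted = gs.label_conversions(impressions, visits, gs.ConversionPolicy())
print(f"impressions: {len(impressions)}, global conversion rate "
      f"{converted.mean():.3f}")

scored = truth.set_index("user_id").join(converted.rename("converted"),
                                         how="inner").reset_index()
scored["score"] = np.clip(scored["latent_risk"]
                          + rng.normal(0, 0.05, len(scored)), 0, 1)
curve = gs.local_show_conversion_rate(
    scored[["user_id", "score", "converted"]], T=201)
rho = spearmanr(curve["percentile"], curve["local_rate"]).statistic
print(f"local-rate curve Spearman rho(percentile, rate) = {rho:.3f}")
# rho near 1 means high-score users convert more: the curve is monotone.

print("bid coefficients:", [round(gs.score_to_coefficient(s), 2)
                            for s in (0.0, 0.5, 1.0)])

labeled = impressions.assign(
    converted=converted.reindex(impressions["user_id"]).to_numpy())
half = len(labeled) // 2
ab = gs.ab_metrics(labeled.head(half), labeled.tail(len(labeled) - half))
print(f"A/B show-conversion change: {ab['show_conversion_change_pct']:+.2f}% "
      f"(random split, so near 0); CPA change {ab['cpa_change_pct']:+.2f}%")
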