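"""Per-zone Bland-Altman agreement between two measurement methods.

Simulates a study-sized measurement table (26 eyes, two observers, two
methods whose values differ by seeded Gaussian noise), then computes the
between-method agreement per zone: mean difference, limits of agreement
with confidence intervals, paired t-test and Pearson correlation.
"""

import numpy as np
import pandas as pd

from okfluor import MeasurementTable, agreement_report, summary_frame

rng = np.random.default_rng(2026)
N_EYES = 26
zone_means = {
    "central_bearing": 4.2, "tear_reservoir": 1.7,
    "mid_peripheral": 1.2, "edge_lift": 0.5,
}

rows = []
for zone, mu in zone_means.items():
    base = rng.normal(mu, 0.15 * mu, N_EYES)
    for method, offset_sd in (("algorithm", (0.0, 0.0)), ("imagej", (-0.05, 0.1))):
        offset, sd = offset_sd
        per_method = base + rng.normal(offset, sd, N_EYES)
        for obs in (1, 2):
            per_obs = per_method + rng.normal(0.0, 0.05, N_EYES)
            for eye, v in enumerate(per_obs):
                rows.append({
                    "eye_id": f"eye{eye:02d}", "observer": obs, "method": method,
                    "zone": zone, "width_mm": max(v, 0.05),
                })
table = MeasurementTable(pd.DataFrame(rows))

report = agreement_report(table, "inter_method")
print("algorithm vs ImageJ (per eye: mean of both observers), n =", N_EYES)
for zone, s in report.items():
    print(f"{zone:<16} diff {s.mean_diff:+.2f} ± {s.sd_diff:.2f} mm  "
          f"LoA [{s.loa_low:+.2f}, {s.loa_high:+.2f}]  "
          f"p = {s.p_value:.2f}  r = {s.pearson_r:.2f}")
print("\nThe mean differences sit near the +0.05 mm offset built into the "
      "simulated ImageJ values, and each LoA spans mean ± 1.96·SD of the "
      "paired differences — the estimator recovers the generating "
      "agreement structure.")

# full table with CIs, as written by `okfluor agree`
print("\n", summary_frame(report).round(3).to_string())
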