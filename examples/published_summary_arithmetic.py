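"""Limits of agreement recomputed from a published difference summary.

Given only a printed paired-difference summary (mean, SD, n) — the form in
which agreement results are usually reported — recompute the Bland-Altman
limits and their confidence intervals, in both the large-sample
approximation and the exact noncentral-t construction.
"""

from okfluor import limits_of_agreement, loa_confidence_interval
from okfluor.stats import AgreementSummary

# inter-observer central-bearing differences from a 26-eye study:
mean_diff, sd_diff, n = -0.16, 0.37, 26

lo, hi = limits_of_agreement(mean_diff, sd_diff)
print(f"difference summary: {mean_diff} ± {sd_diff} mm (n = {n})")
print(f"limits of agreement: [{lo:.2f}, {hi:.2f}] mm")

summary = AgreementSummary(
    n=n, mean_diff=mean_diff, sd_diff=sd_diff, loa_low=lo, loa_high=hi,
    loa_low_ci=(0, 0), loa_high_ci=(0, 0), t_stat=0.0, df=n - 1, p_value=1.0,
    pearson_r=None, r_p_value=None, mean_a=0, sd_a=1, ci_a=(0, 0),
    mean_b=0, sd_b=1, ci_b=(0, 0),
)
for mode in ("approximate", "exact"):
    (lo_lo, lo_hi), (hi_lo, hi_hi) = loa_confidence_interval(summary, mode=mode)
    print(f"{mode:>12} 95% CI: lower limit [{lo_lo:.2f}, {lo_hi:.2f}], "
          f"upper limit [{hi_lo:.2f}, {hi_hi:.2f}]")
print("\nThe interval around each limit reflects how precisely n pairs pin "
      "down the population 2.5%/97.5% difference quantiles; the exact "
      "interval is asymmetric because the limit estimate couples the mean "
      "and SD.")
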