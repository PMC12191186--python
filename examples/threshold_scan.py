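"""Locate candidate FIT triage thresholds by cumulative-count scanning.

The CUSUM scan counts urgent conversions at or below each FIT threshold in
0.1 µg/g steps; one-step increases of ≥5 cases are jump points.  The
incremental significance scan then compares rising-FIT patients (10 < FIT ≤ t)
against the low-FIT group (FIT ≤ 10) for each t in 11-29 µg/g.
"""

from fittriage import (
    SyntheticParams,
    conversion_rate_at,
    cusum_scan,
    generate_cohort,
    incremental_significance_scan,
)

cohort = generate_cohort(SyntheticParams(n=1531, seed=1))

scan = cusum_scan(cohort, step=0.1, min_jump=5)
print(f"jump points (µg/g): {', '.join(f'{t:g}' for t in scan.jump_points)}")
for t in scan.jump_points:
    print(f"  FIT ≤ {t:6g}: conversion rate {100 * conversion_rate_at(scan, t):.1f}%")
print()

sig = incremental_significance_scan(cohort, g1_max=10, scan_lo=11, scan_hi=29)
evaluable = sig.rows[~sig.rows["flagged"]]
for row in evaluable.itertuples():
    marker = " *" if row.p_value < sig.alpha else ""
    print(f"  t = {row.t:4.0f}: OR {row.odds_ratio:5.2f} "
          f"({row.ci_low:.2f}-{row.ci_high:.2f}), p = {row.p_value:.3f}{marker}")
print(f"first persistently significant threshold: {sig.first_sustained} µg/g")
print()
print("Jump points at 7, 10 and 400 µg/g reflect assay detection limits where")
print("imputation stacks patients; interior jumps mark risk inflections. The")
print("starred rows are significant at the 5% level; the reported threshold")
print("is the lowest t that stays significant at every larger t in range.")
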