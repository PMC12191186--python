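"""Sample size for detecting a FIT difference between pathology groups.

Solves the two-sided two-sample t-test design: expected difference 20 µg/g,
common SD 117 µg/g (Cohen's d ≈ 0.171), alpha 0.05, power 0.90.
"""

from fittriage import PowerSpec, sample_size_two_sample_t

spec = PowerSpec(delta=20.0, sd=117.0, alpha=0.05, power=0.90)
res = sample_size_two_sample_t(spec)

print(f"Cohen's d                 : {spec.cohen_d:.4f}")
print(f"per-group n (continuous)  : {res.per_group_continuous:.2f}")
print(f"per-group n (normal appr.): {res.per_group_normal_approx:.2f}")
print(f"total N (ceil of 2n)      : {res.total}")
print()
print("The total is the number of patients needed so that a two-sample")
print("t-test has 90% power to detect the expected FIT difference between")
print("patients with and without significant colonic findings.")
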