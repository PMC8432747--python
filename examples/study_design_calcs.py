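"""Design calculations for a family study of disease heritability.

Power: with 1,152 individuals and a relatedness variance of 0.00015 the
study detects a heritability as low as 0.3 with power 0.8492.  Sample size:
detecting a prevalence of 8.7% against a 6.7% reference (alpha 0.05, power
0.80) needs 1,323 individuals.
"""

from famvc import PowerSpec, greml_power, prevalence_sample_size

power = greml_power(PowerSpec(n=1152, var_pi=0.00015, h2_target=0.3, alpha=0.05))
print(f"post-hoc power for h2 = 0.3 at n = 1152: {power:.4f}")

n = prevalence_sample_size(p0=0.067, p1=0.087, alpha=0.05, power=0.80)
print(f"sample size to detect 8.7% vs 6.7% prevalence: {n}")
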