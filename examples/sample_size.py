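"""How many subjects does a test-retest reliability study need?

Evaluates the Walter-Eliasziw-Donner approximation for two measurements
per subject (one-sided alpha 0.05, power 80%) across target ICC values.
Small ICCs demand large cohorts: detecting ICC = 0.20 takes 152 subjects,
which is why small studies over-report high reliability.
"""

from connrel import icc_sample_size

print("target ICC -> minimum subjects (k=2, alpha=0.05 one-sided, power=0.80)")
for rho1 in (0.10, 0.20, 0.30, 0.40, 0.50, 0.75):
    n = icc_sample_size(rho1, rho0=0.0, k=2, alpha=0.05, power=0.80)
    print(f"  ICC = {rho1:.2f}: n >= {n}")
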