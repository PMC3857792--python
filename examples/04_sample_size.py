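"""Plan a study comparing two dehydration scales by AUC.

How many children must be enrolled to detect a 0.2 difference in AUC
(0.70 vs 0.90) with two-sided alpha 0.05 and power 0.80, when only ~9% of
children are expected to have severe disease?
"""

from dehydrakit import SampleSizePlan, achieved_power, required_n

plan = SampleSizePlan(auc1=0.70, auc2=0.90, alpha=0.05, power=0.80,
                      positive_fraction=0.09)
n = required_n(plan)
print(f"required total n = {n}")
print(f"achieved power at n:   {achieved_power(plan, n):.3f}")
print(f"achieved power at n-1: {achieved_power(plan, n - 1):.3f}")

# With a common outcome (50% positive) far fewer children suffice:
balanced = SampleSizePlan(auc1=0.70, auc2=0.90, positive_fraction=0.5)
print(f"same design at 50% outcome prevalence: n = {required_n(balanced)}")

# Rare outcomes dominate the variance of both AUC estimates, so the
# requirement scales roughly with 1/prevalence: 295 children at 9%
# prevalence versus 75 at 50%.
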