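"""Derive the criterion-standard outcome from daily weights.

A dehydrated child gains weight under rehydration until reaching the
pre-illness weight, then plateaus. The stable weight is the mean of the
highest two consecutive daily weights differing by less than 2%; percent
weight change with rehydration proxies the percent volume deficit.
"""

from dehydrakit import (
    WeightSeries,
    classify_dehydration,
    find_stable_weight,
    percent_weight_change,
    severe_disease_outcome,
)

daily_kg = [8.0, 8.6, 8.95, 9.02, 8.99]  # day 0 (admission) .. day 4
series = WeightSeries.from_weights(daily_kg)

res = find_stable_weight(series)
print(f"status: {res.status.value}; stable weight: {res.stable_weight:.3f} kg "
      f"(days {res.pair_indices[0]}-{res.pair_indices[1]})")

pct = percent_weight_change(series.admission_weight, res.stable_weight)
print(f"percent weight change with rehydration: {pct:.1f}%")
print(f"dehydration category: {classify_dehydration(pct).value}")

out = severe_disease_outcome(series, died=False)
print(f"composite severe-disease outcome: {out.severe_disease.value}")

# Days 3 and 4 differ by 0.3% and have the greatest mean, so the stable
# weight is 9.005 kg. The child gained 11.2% of that weight back -> severe
# dehydration (>= 10%), hence outcome-positive even though the child lived.
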