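"""Score one child on the three dehydration scales.

A 9-month-old arrives lethargic with very sunken eyes, unable to drink, and
a skin pinch that goes back in under two seconds. Each scale reads the same
canonical sign observations and reaches its own verdict.
"""

from dehydrakit import (
    DEFAULT_CUTPOINTS,
    ObservationSet,
    classify,
    score_cdc,
    score_cds,
    score_who,
)

child = ObservationSet(
    mental_status=2,   # lethargic or unconscious
    thirst=2,          # unable to drink
    heart_rate=1,      # increased
    pulse_quality=1,   # decreased
    breathing=0,
    eyes=2,            # very sunken
    tears=2,           # absent
    mouth_tongue=2,    # very dry
    skin_recoil=1,     # recoil < 2 s
    capillary_refill=1,
    extremities=1,
    urine_output=2,
)

for scorer, scale in ((score_who, "WHO"), (score_cdc, "CDC"), (score_cds, "CDS")):
    s = scorer(child)
    cut = DEFAULT_CUTPOINTS[scale]
    verdict = "POSITIVE" if classify(s, cut) else "negative"
    print(f"{scale:>3}: {s.points:>2}/{s.max_points} points  "
          f"(severe-disease cut-point >={cut}: {verdict})")

# The WHO scale scores this child 3/4 (skin recoil under 2 s is not "very
# slow", so the skin-pinch item contributes nothing), the CDC scale 17/24 and
# the CDS 8/8; all three exceed their published severe-disease cut-points.
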