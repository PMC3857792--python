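# Methods

## The problem and the measurement model

Bedside dehydration scales summarize ordinal clinical signs into a score
meant to predict severe disease — severe dehydration or death — in children
admitted with acute diarrhea. Validating such a scale requires an objective
reference for how dehydrated each child actually was. The accepted reference
is *percent weight change with rehydration*: a dehydrated child gains weight
as fluid is replaced until reaching the pre-illness weight, then plateaus
while the kidneys diurese any excess. The fraction of body weight regained
approximates the fraction of body volume lost.

All three scales are computed from one canonical observation set of twelve
signs, each at ordinal level 0/1/2 (well → worst):

- **CDC scale**: the sum of all twelve levels, range 0–24.
- **WHO severe dehydration scale**: four binary items (abnormally altered
  mental status, sunken eyes, inability to drink, very slow skin pinch),
  range 0–4; ≥2 points defines severe dehydration. When the examiner did not
  chart the WHO items directly they are derived from the ordinal signs:
  mental status level 2 → 1 point; eyes level ≥1 → 1 point (the WHO wording
  dichotomizes "sunken" vs normal, and slightly sunken eyes are not normal —
  a `who_eyes_strict` switch restricts the mapping to level 2); thirst
  level 2 → 1 point (level 1, eager drinking, is explicitly non-scoring in
  the WHO wording); skin recoil level 2 → 1 point.
- **Clinical Dehydration Scale (CDS)**: general appearance + eyes + mucous
  membranes (the mouth-and-tongue sign) + tears, range 0–8. General
  appearance is 2 when the child is lethargic/unconscious, 1 when restless,
  irritable or abnormally thirsty (mirroring the scale's level-1 wording
  "thirsty, restless, or irritable"), else 0.

Point maps are data (`data/scale_definitions.json`), not code. Scores with
any missing constituent are flagged incomplete and excluded per scale —
never imputed and never silently zero — so analysis n can differ by scale
and is reported in the run manifest.

## Criterion standard

The *stable weight* is the mean of the two consecutive daily weights, with
relative difference below 2%, whose mean is greatest ("highest two
consecutive weights"); ties go to the later pair. The relative difference is
taken over the pair mean (symmetric; a `denominator="larger"` switch gives
the more permissive alternative). Percent weight change is
`(stable − admission)/stable × 100`, banded <2% (none), 2–10% (some),
≥10% (severe). The band edge at exactly 10% counts as severe ("10% or
more"); a `severe_inclusive=False` switch implements the strictly-greater
convention. Children who died are outcome-positive regardless of weights —
the most severely dehydrated children rarely survive to a stable weight, and
dropping them would bias every scale toward the null. Surviving children
with no qualifying pair are classified gaining (last ≥ first weight), losing
or single-weight, and are indeterminate: excluded from accuracy analyses but
counted in the manifest.

## Accuracy evaluation

Positivity is `score ≥ threshold` throughout. The empirical ROC has one
operating point per distinct score plus a sentinel, so the degenerate
endpoints are always present. The AUC is computed by midranks (the
Mann–Whitney probability with ties counted half), which equals the
trapezoidal area under the empirical curve exactly; the test suite asserts
the equality to 1e−12 and cross-checks against scikit-learn. Standard errors
and 95% CIs use the Hanley–McNeil formula (exponential kernel,
Q₁ = A/(2−A), Q₂ = 2A²/(1+A)); a scale is called a significant predictor
when the CI lower bound exceeds 0.5. This SE choice matters: with patient
data unavailable, published CIs computed by other nonparametric estimators
are not exactly reproducible, so the package treats CI width as
method-defined rather than a target. Simulated coverage at the study's class
sizes (13 positive / 127 negative, binormal truth 0.8) is ~96%.

Best cut-points maximize sensitivity subject to specificity strictly above a
floor (default 50%) — missing severe disease is costlier than
over-triaging — with ties resolved toward higher specificity, then lower
threshold. Sensitivity and specificity get Wald intervals, switching to
exact Clopper–Pearson at boundary estimates (a 100% sensitivity row reports
an exact lower bound). Likelihood ratios use the ratio identities with
log-method intervals, `Var(ln LR+) = (1−se)/(se·n₊) + sp/((1−sp)·n₋)` and
its mirror; non-calculable quantities (zero denominators, boundary LR−) are
flagged NC rather than approximated. Baseline group comparisons use the
Mann–Whitney U test (exact enumeration of group assignments when combined
n ≤ 10, which remains valid under ties; tie-corrected normal approximation
otherwise) and the Pearson chi-square test without continuity correction
(switchable). Subgroup AUC tables stratify by examiner type and by age,
with the 12-month boundary child assigned to the older stratum ("younger
than twelve months" is strict). No multiple-comparison adjustment is
applied anywhere, matching the exploratory character of the subgroup
analyses.

## Sample size for comparing two AUCs

`required_n` solves the standard two-curve comparison
`n₊ = (z_{α/2}√(2V̄) + z_β√(V₁+V₂))²/ΔA²` with the per-positive Hanley
variance kernel evaluated at the expected negative:positive ratio, converts
to a total via the outcome prevalence, then refines against forward-computed
power using the finite-sample Hanley SE so the returned n is the minimal
total meeting the requested power (the asymptotic formula can land one or
two children off in either direction). A correlation r between the two AUC
estimates is accepted; it defaults to 0, which is conservative for scales
measured on the same children. The tie between this kernel and the one used
for CIs keeps the design and analysis internally consistent.

## Synthetic cohort

The generator emulates the structure the analysis assumes, with defaults
reflecting a rural low-income-country inpatient diarrhea cohort:

| parameter | default | meaning |
|---|---|---|
| `severity_mixture` | (0.51, 0.42, 0.07) | P(no / some / severe latent deficit) |
| `deficit_bands` | (0–2, 2–10, 10–15) % | uniform deficit within category |
| `death_prob_given_severe` | 0.30 | → ~2.1% overall mortality |
| `malnutrition_fraction` | 0.15 | severe wasting or edema |
| `malnourished_gaining/losing_frac` | 0.35 / 0.45 | trajectory type mix |
| `provider_nurse_fraction` | 0.45 | examiner mix |
| `nurse_noise_epsilon` | 0.25 | emission rows mixed toward uniform for nurses |
| `plateau_tau_days` | 1.0 d | rehydration time constant |
| `weight_noise_sd` | 0.003 | scale noise, fraction of W0 |
| `single_weight_prob` | 0.045 | discharged within a day |
| `age_median_months`, `age_log_sigma` | 10, 0.9 | lognormal ages, clipped 1–144 m |
| `stay_length_mean_days` | 5 (Poisson, clipped 2–10) | daily weights per child |

Rehydrated children follow `W(d) = W0·(1 − (v/100)e^{−d/τ})·(1+ε_d)`, which
stabilizes (consecutive difference < 2%) by day 2–3 for realistic deficits —
matching the observed median of about two days to a stable weight.
Malnourished gaining/losing children change at a constant relative rate
anchored to the configured kg/day at admission (0.35/0.30 kg/day), large
enough that they rarely produce a qualifying pair; deaths truncate the
series after one or two declining measurements. Signs are drawn from
category-conditional emission rows — default (0.50, 0.35, 0.15) /
(0.40, 0.40, 0.20) / (0.30, 0.40, 0.30), overridable per sign — chosen to
yield the moderate discrimination (AUC ≈ 0.65–0.80) bedside scales actually
show; nurse-examined children use rows mixed toward uniform by ε, a
one-parameter mechanism for a provider accuracy gap that is agnostic about
its cause. The examiner's overall clinical impression is a weakly
informative category-conditional Bernoulli (rates 0.12/0.18/0.28), so it
tracks severity far worse than the scales do.

What the generator deliberately does **not** model: dependence among signs
beyond the shared severity category (signs are conditionally independent
given severity — real signs co-vary within physiologic clusters), etiology
and treatment effects, age-dependent sign prevalence, diuresis dips after
the plateau, or calibrated mortality risk models. Passing recovery tests
therefore demonstrates that the *pipeline* measures what it claims on data
with this structure, not that any scale has a particular accuracy in real
children.

`oracle_auc` scores a 50,000-child cohort from the same configuration
against the *latent* outcome (severe category or death) and serves as the
recovery target: the full pipeline — scoring, stable-weight derivation,
exclusions, measured outcome — run on ten seeded 2,000-child cohorts
recovers it to within ±0.05 on the replicate mean. Single replicates carry
AUC sampling error of ~0.02–0.03 at 7% outcome prevalence, so the recovery
bound is asserted on the mean; the per-replicate spread is reported
alongside. The stable-weight estimator recovers the true pre-illness weight
within 1% for every tested trajectory at measurement noise 0.3% of W0; at
0.5% noise, choosing the greatest qualifying pair mean carries a positive
selection bias on the order of the per-pair noise SD, so about 1% of
trajectories stray past 1% error — the tests assert the strict bound at the
lower noise level and a 95%-of-trajectories bound with mean error < 0.5% at
the higher one.

## Numerical conventions and degenerate inputs

Empty series, non-positive weights, single-class outcomes, zero-marginal
contingency tables and infeasible cut-point floors raise informative errors;
they are never coerced. A degenerate AUC of exactly 0 or 1 yields SE 0 with
a warning. Configuration objects validate eagerly and name the offending
field. All randomness flows through `numpy.random.default_rng` seeds;
identical seeds reproduce every table byte-for-byte, and the run manifest
records the configuration, analysis n per scale and exclusion counts needed
to re-run any analysis exactly.

## Problem sizes used in verification

Brute-force agreement checks use 10,000 random weight series and 1,000 tied
ROC instances; CI coverage uses 2,000 replicates at class sizes 13/127;
end-to-end recovery uses ten 2,000-child cohorts per scale against a
50,000-child oracle. These sizes give the binomial/Monte-Carlo margins
quoted above while keeping the full suite under a minute of compute.
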