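"""Synthetic cohort generator for children admitted with acute diarrhea.

Each child carries a latent dehydration state: a severity category
(no / some / severe dehydration) with a continuous percent volume deficit v
drawn within the category's band. Observable data are generated from that
latent truth:

* clinical signs — each of the twelve ordinal signs is drawn from a
  category-conditional emission distribution (conditionally independent
  given severity); for nurse-examined children every emission row is mixed
  toward the uniform distribution by a noise parameter epsilon, emulating
  less reliable sign ascertainment without asserting its cause;
* weight trajectories — rehydrated children follow
  W(d) = W0 * (1 - (v/100) * exp(-d/tau)) * (1 + noise), rising to a plateau
  at the pre-illness weight W0 within two to three days; severely
  malnourished children may instead gain steadily (protein-energy
  supplementation, wasting) or lose steadily (diuresis of edema) with no
  plateau; children who die have their series truncated before any plateau;
  a small fraction are discharged within a day and have a single weight;
* the examiner's overall clinical impression — a weakly informative
  category-conditional coin flip.

Alongside the observable cohort table the generator returns a truth table
(latent deficit, pre-illness weight, category, trajectory type) so recovery
of known ground truth can be tested at every pipeline stage.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .scales import CDC_ITEMS

__all__ = ["CohortConfig", "generate_cohort", "oracle_auc", "COHORT_SIGN_COLUMNS"]

COHORT_SIGN_COLUMNS = [f"cdc_{item}" for item in CDC_ITEMS]
WHO_COLUMNS = ["who_mental", "who_eyes", "who_thirst", "who_skin_pinch"]

CATEGORY_NAMES = ("none", "some", "severe")


class CohortConfig(BaseModel):
    """Parameters of the synthetic cohort; defaults mirror the structure of a
    rural low-income-country inpatient diarrhea cohort (median age ~10 months,
    roughly half with no dehydration, ~7% severe, ~2% mortality, 15% severe
    malnutrition, 45% of exams by nurses)."""

    n: int = Field(178, ge=1)
    seed: int = 0

    # latent severity: P(no / some / severe dehydration) and deficit bands (%)
    severity_mixture: tuple[float, float, float] = (0.51, 0.42, 0.07)
    deficit_bands: tuple[tuple[float, float], ...] = ((0.0, 2.0), (2.0, 10.0), (10.0, 15.0))
    death_prob_given_severe: float = Field(0.30, ge=0.0, le=1.0)

    # population structure
    malnutrition_fraction: float = Field(0.15, ge=0.0, le=1.0)
    malnourished_gaining_frac: float = Field(0.35, ge=0.0, le=1.0)
    malnourished_losing_frac: float = Field(0.45, ge=0.0, le=1.0)
    provider_nurse_fraction: float = Field(0.45, ge=0.0, le=1.0)
    male_fraction: float = Field(0.59, ge=0.0, le=1.0)
    gastroenteritis_fraction: float = Field(0.62, ge=0.0, le=1.0)
    single_weight_prob: float = Field(0.045, ge=0.0, le=1.0)

    # sign emission: rows are P(level | category) for levels 0/1/2; one
    # shared matrix, with optional per-sign overrides keyed by CDC item name
    emission: tuple[tuple[float, float, float], ...] = (
        (0.50, 0.35, 0.15),
        (0.40, 0.40, 0.20),
        (0.30, 0.40, 0.30),
    )
    per_sign_emission: Optional[dict[str, tuple[tuple[float, float, float], ...]]] = None
    nurse_noise_epsilon: float = Field(0.25, ge=0.0, le=1.0)
    impression_severe_rates: tuple[float, float, float] = (0.12, 0.18, 0.28)

    # weight trajectories
    plateau_tau_days: float = Field(1.0, gt=0.0)
    gain_kg_per_day: float = Field(0.35, gt=0.0)
    loss_kg_per_day: float = Field(0.30, gt=0.0)
    weight_noise_sd: float = Field(0.003, ge=0.0)  # fraction of W0

    # demographics / stay
    age_median_months: float = Field(10.0, gt=0.0)
    age_log_sigma: float = Field(0.9, gt=0.0)
    age_range_months: tuple[float, float] = (1.0, 144.0)
    stay_length_mean_days: float = Field(5.0, gt=0.0)
    stay_length_max_days: int = Field(10, ge=2)

    @field_validator("severity_mixture", "impression_severe_rates")
    @classmethod
    def _check_probs(cls, v):
        if any(not 0.0 <= p <= 1.0 for p in v):
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @field_validator("severity_mixture")
    @classmethod
    def _check_mixture(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("severity_mixture must sum to 1")
        return v

    @model_validator(mode="after")
    def _check_rest(self):
        if self.malnourished_gaining_frac + self.malnourished_losing_frac > 1.0 + 1e-9:
            raise ValueError("malnourished gaining + losing fractions exceed 1")
        for band in self.deficit_bands:
            if band[0] > band[1] or band[0] < 0:
                raise ValueError(f"invalid deficit band {band}")
        for row in self._emission_rows():
            if abs(sum(row) - 1.0) > 1e-9 or any(p < 0 for p in row):
                raise ValueError("emission rows must be non-negative and sum to 1")
        return self

    def _emission_rows(self):
        rows = list(self.emission)
        if self.per_sign_emission:
            for mat in self.per_sign_emission.values():
                rows.extend(mat)
        return rows


def _median_weight_for_age(age_months: np.ndarray) -> np.ndarray:
    # piecewise-linear approximation of a median weight-for-age curve (kg)
    young = 3.3 + 0.55 * np.minimum(age_months, 12.0)
    return young + 0.21 * np.maximum(age_months - 12.0, 0.0)


def _sample_levels(rng, p_row: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Ordinal level per child from per-child probability rows via one uniform."""
    c1 = p_row[:, 0]
    c2 = p_row[:, 0] + p_row[:, 1]
    return (u >= c1).astype(int) + (u >= c2).astype(int)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort table, truth table), deterministically from the seed.

    The cohort table follows the analysis CSV schema: demographics, examiner,
    twelve ``cdc_*`` ordinal sign columns, four binary ``who_*`` columns,
    overall clinical impression, death and malnutrition flags, and wide daily
    weight columns ``weight_d0 .. weight_dK`` (NaN once discharged). The truth
    table holds each child's latent deficit, pre-illness weight, category and
    trajectory type.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    cat = rng.choice(3, size=n, p=np.asarray(config.severity_mixture))
    bands = np.asarray(config.deficit_bands)
    v = rng.uniform(bands[cat, 0], bands[cat, 1])

    age = np.exp(rng.normal(np.log(config.age_median_months), config.age_log_sigma, n))
    age = np.clip(age, *config.age_range_months)
    male = rng.random(n) < config.male_fraction
    nurse = rng.random(n) < config.provider_nurse_fraction
    malnourished = rng.random(n) < config.malnutrition_fraction
    gastro = rng.random(n) < config.gastroenteritis_fraction

    died = (cat == 2) & (rng.random(n) < config.death_prob_given_severe)
    single = ~died & (rng.random(n) < config.single_weight_prob)

    traj = np.full(n, "plateau", dtype=object)
    u_m = rng.random(n)
    gaining = malnourished & (u_m < config.malnourished_gaining_frac)
    losing = malnourished & ~gaining & (
        u_m < config.malnourished_gaining_frac + config.malnourished_losing_frac
    )
    traj[gaining] = "gaining"
    traj[losing] = "losing"
    traj[single] = "single"
    traj[died] = "death"

    w0 = _median_weight_for_age(age) * np.exp(rng.normal(0.0, 0.12, n))

    # length of stay: number of daily weights is stay+1 (day 0 = admission)
    stay = np.clip(
        rng.poisson(config.stay_length_mean_days, n), 2, config.stay_length_max_days
    )
    stay[traj == "single"] = 0
    stay[traj == "death"] = rng.integers(0, 2, n)[traj == "death"]

    max_day = int(stay.max())
    days = np.arange(max_day + 1)
    noise = 1.0 + rng.normal(0.0, config.weight_noise_sd, (n, max_day + 1))

    base = w0[:, None] * (1.0 - (v[:, None] / 100.0) * np.exp(-days[None, :] / config.plateau_tau_days))
    admission = w0 * (1.0 - v / 100.0)
    is_gain = traj == "gaining"
    is_lose = traj == "losing"
    is_death = traj == "death"
    # malnourished non-plateau trajectories change by a constant relative
    # rate anchored to the configured kg/day at the admission weight, so the
    # series stays positive and never flattens into a spurious stable pair
    r_gain = config.gain_kg_per_day / admission[is_gain]
    base[is_gain] = admission[is_gain, None] * (1.0 + r_gain[:, None]) ** days[None, :]
    r_lose = config.loss_kg_per_day / admission[is_lose]
    base[is_lose] = admission[is_lose, None] * (1.0 - np.minimum(r_lose, 0.15)[:, None]) ** days[None, :]
    # children who die deteriorate; no rehydration plateau is reached
    base[is_death] = admission[is_death, None] * (1.0 - 0.02 * days[None, :])
    weights = base * noise
    weights[days[None, :] > stay[:, None]] = np.nan

    # clinical signs: emission row by (category, examiner); nurses mix toward uniform
    eps = config.nurse_noise_epsilon
    emission = np.asarray(config.emission)
    sign_levels = {}
    u_signs = rng.random((n, len(CDC_ITEMS)))
    for j, item in enumerate(CDC_ITEMS):
        mat = emission
        if config.per_sign_emission and item in config.per_sign_emission:
            mat = np.asarray(config.per_sign_emission[item])
        rows = mat[cat]
        rows = np.where(nurse[:, None], (1.0 - eps) * rows + eps / 3.0, rows)
        sign_levels[f"cdc_{item}"] = _sample_levels(rng, rows, u_signs[:, j])

    impression = rng.random(n) < np.asarray(config.impression_severe_rates)[cat]

    cohort = pd.DataFrame({"child_id": [f"C{i:05d}" for i in range(n)]})
    cohort["age_months"] = np.round(age, 1)
    cohort["sex"] = np.where(male, "M", "F")
    cohort["provider"] = np.where(nurse, "nurse", "physician")
    for col, levels in sign_levels.items():
        cohort[col] = levels
    # the examiner charts the WHO items consistently with the ordinal signs
    cohort["who_mental"] = (cohort["cdc_mental_status"] == 2).astype(int)
    cohort["who_eyes"] = (cohort["cdc_eyes"] >= 1).astype(int)
    cohort["who_thirst"] = (cohort["cdc_thirst"] == 2).astype(int)
    cohort["who_skin_pinch"] = (cohort["cdc_skin_recoil"] == 2).astype(int)
    cohort["clinical_impression_severe"] = impression.astype(int)
    cohort["died"] = died.astype(int)
    cohort["severe_malnutrition"] = malnourished.astype(int)
    cohort["discharge_diagnosis"] = np.where(gastro, "gastroenteritis", "other")
    for d in range(max_day + 1):
        cohort[f"weight_d{d}"] = np.round(weights[:, d], 3)

    truth = pd.DataFrame(
        {
            "child_id": cohort["child_id"],
            "deficit_pct": np.round(v, 3),
            "w0_kg": np.round(w0, 3),
            "true_category": [CATEGORY_NAMES[c] for c in cat],
            "died": died.astype(int),
            "trajectory_type": traj,
        }
    )
    return cohort, truth


def true_severe_disease(truth: pd.DataFrame) -> pd.Series:
    """Latent composite outcome: severe-category deficit or death."""
    return ((truth["true_category"] == "severe") | (truth["died"] == 1)).astype(int)


def oracle_auc(config: CohortConfig, scale_id: str, n_large: int = 50_000) -> float:
    """Ground-truth AUC of a scale against the latent severe-disease outcome,
    estimated on a large cohort drawn from the same configuration.

    Used as the recovery target for end-to-end pipeline tests: the pipeline's
    AUC on a finite cohort (with its criterion-standard misclassification and
    indeterminate exclusions) should land near this value.
    """
    from .pipeline import score_cohort  # local import to avoid a cycle

    big = config.model_copy(update={"n": n_large})
    cohort, truth = generate_cohort(big)
    scored = score_cohort(cohort)
    col = f"score_{scale_id.lower()}"
    y = true_severe_disease(truth)
    from .evaluation import auc_mann_whitney

    valid = scored[col].notna()
    return auc_mann_whitney(
        scored.loc[valid, col].to_numpy(float), y[valid].to_numpy()
    )
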