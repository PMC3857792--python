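"""End-to-end orchestration: score the cohort on all three scales, derive the
criterion-standard outcome from daily weights, and produce the full accuracy
report (per-child table, best-cut-point test characteristics, stratified AUC
table, baseline comparison tables, run manifest).

Exclusions are reported, never silent: the manifest counts children without a
stable weight (gaining / losing / single-weight) and incomplete scores per
scale, mirroring a study flow diagram.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .criterion import (
    SevereDisease,
    WeightSeries,
    severe_disease_outcome,
)
from .evaluation import (
    ContingencyTable,
    best_cutpoint,
    chi_square_test,
    empirical_roc,
    impression_characteristics,
    mann_whitney_test,
    subgroup_report,
    test_characteristics,
)
from .scales import CDC_ITEMS

SCALE_SCORE_COLUMNS = {"WHO": "score_who", "CDC": "score_cdc", "CDS": "score_cds"}

REQUIRED_COLUMNS = ["child_id", "age_months", "sex", "provider", "died"] + [
    f"cdc_{item}" for item in CDC_ITEMS
]


class RunConfig(BaseModel):
    """Convention switches and reproducibility settings for a full run."""

    spec_floor: float = Field(0.5, ge=0.0, lt=1.0)
    severe_boundary_inclusive: bool = True  # 10.0% counts as severe
    who_eyes_strict: bool = False  # map only "very sunken" to WHO sunken eyes
    pair_denominator: Literal["mean", "larger"] = "mean"
    stable_rel_tol: float = Field(0.02, gt=0.0, lt=1.0)
    age_boundary_months: float = 12.0
    cutpoints: Optional[dict[str, int]] = None  # pin instead of ROC-derived
    seed: int = 0


# ---------------------------------------------------------------------------
# vectorized scoring (semantically identical to scales.score_*)


def score_cohort(cohort: pd.DataFrame, *, prefer_direct: bool = True,
                 eyes_strict: bool = False) -> pd.DataFrame:
    """Add ``score_who``, ``score_cdc``, ``score_cds`` columns (NaN where a
    constituent sign is missing). Vectorized but equivalent to scoring each
    row through :mod:`dehydrakit.scales`."""
    df = cohort.copy()
    cdc_cols = [f"cdc_{item}" for item in CDC_ITEMS]
    cdc = df[cdc_cols].apply(pd.to_numeric, errors="coerce")
    df["score_cdc"] = cdc.sum(axis=1, skipna=False)

    derived = pd.DataFrame(index=df.index)
    derived["who_mental"] = (cdc["cdc_mental_status"] == 2).astype(float).where(cdc["cdc_mental_status"].notna())
    eyes_pos = cdc["cdc_eyes"] == 2 if eyes_strict else cdc["cdc_eyes"] >= 1
    derived["who_eyes"] = eyes_pos.astype(float).where(cdc["cdc_eyes"].notna())
    derived["who_thirst"] = (cdc["cdc_thirst"] == 2).astype(float).where(cdc["cdc_thirst"].notna())
    derived["who_skin_pinch"] = (cdc["cdc_skin_recoil"] == 2).astype(float).where(cdc["cdc_skin_recoil"].notna())
    who = pd.DataFrame(index=df.index)
    for col in derived.columns:
        direct = pd.to_numeric(df[col], errors="coerce") if col in df.columns else pd.Series(np.nan, index=df.index)
        who[col] = direct.where(direct.notna(), derived[col]) if prefer_direct else derived[col].where(derived[col].notna(), direct)
    df["score_who"] = who.sum(axis=1, skipna=False)

    ga = pd.Series(np.nan, index=df.index)
    m, t = cdc["cdc_mental_status"], cdc["cdc_thirst"]
    ok = m.notna() & t.notna()
    ga[ok] = np.select([m[ok] == 2, (m[ok] == 1) | (t[ok] >= 1)], [2, 1], default=0)
    df["score_cds"] = ga + cdc["cdc_eyes"] + cdc["cdc_mouth_tongue"] + cdc["cdc_tears"]
    return df


# ---------------------------------------------------------------------------
# criterion standard over the cohort table


def weight_columns(cohort: pd.DataFrame) -> list[tuple[int, str]]:
    pairs = []
    for col in cohort.columns:
        m = re.fullmatch(r"weight_d(\d+)", col)
        if m:
            pairs.append((int(m.group(1)), col))
    return sorted(pairs)


def weight_series_from_row(row: pd.Series, day_cols: list[tuple[int, str]]) -> Optional[WeightSeries]:
    days, weights = [], []
    for day, col in day_cols:
        w = row[col]
        if pd.notna(w):
            days.append(day)
            weights.append(float(w))
    if not days:
        return None
    return WeightSeries(tuple(days), tuple(weights))


def criterion_outcomes(cohort: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-child criterion-standard table: stable-weight status, percent
    weight change, dehydration category and composite severe-disease outcome."""
    config = config or RunConfig()
    day_cols = weight_columns(cohort)
    if not day_cols:
        raise ValueError("cohort has no weight_d<k> columns")
    records = []
    for _, row in cohort.iterrows():
        series = weight_series_from_row(row, day_cols)
        if series is None:
            raise ValueError(f"child {row['child_id']}: no weight measurements")
        out = severe_disease_outcome(
            series,
            bool(row["died"]),
            rel_tol=config.stable_rel_tol,
            denominator=config.pair_denominator,
            severe_inclusive=config.severe_boundary_inclusive,
        )
        records.append(
            {
                "child_id": row["child_id"],
                "weight_status": out.status.value,
                "percent_weight_change": out.percent_weight_change,
                "dehydration_category": out.category.value if out.category else None,
                "severe_disease": out.severe_disease.value,
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class ReportBundle:
    per_child: pd.DataFrame
    accuracy_table: pd.DataFrame
    stratified_auc: pd.DataFrame
    baseline_stable: pd.DataFrame
    baseline_provider: pd.DataFrame
    impression_table: pd.DataFrame
    roc_points: dict[str, pd.DataFrame]
    manifest: dict


def validate_cohort_schema(cohort: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {', '.join(missing)}")
    if not weight_columns(cohort):
        raise ValueError("cohort is missing weight_d<k> columns")
    for item in CDC_ITEMS:
        col = f"cdc_{item}"
        vals = pd.to_numeric(cohort[col], errors="coerce").dropna()
        bad = ~vals.isin([0, 1, 2])
        if bad.any():
            idx = vals[bad].index[0]
            raise ValueError(f"column {col}, row {idx}: sign level must be 0, 1 or 2")


def _binary_outcome(per_child: pd.DataFrame) -> pd.Series:
    return per_child["severe_disease"].map(
        {SevereDisease.POSITIVE.value: 1, SevereDisease.NEGATIVE.value: 0}
    )


def _baseline_row(name, val_a, val_b, p):
    return {"characteristic": name, "group_a": val_a, "group_b": val_b, "p_value": p}


def _compare_groups(df: pd.DataFrame, mask_a: pd.Series, labels: tuple[str, str],
                    extra: Optional[list[tuple[str, pd.Series]]] = None) -> pd.DataFrame:
    """Baseline-characteristic comparison of two subgroups (median age by
    Mann-Whitney; binary characteristics by chi-square)."""
    a, b = df[mask_a], df[~mask_a]
    rows = []
    _, p_age = mann_whitney_test(a["age_months"].to_numpy(float), b["age_months"].to_numpy(float))
    rows.append(_baseline_row("age_median_months", a["age_months"].median(), b["age_months"].median(), p_age))
    binaries = [
        ("male_pct", df["sex"] == "M"),
        ("gastroenteritis_pct", df["discharge_diagnosis"] == "gastroenteritis"),
        ("severe_malnutrition_pct", df["severe_malnutrition"] == 1),
    ] + (extra or [])
    for name, flag in binaries:
        fa, fb = flag[mask_a], flag[~mask_a]
        table = [[fa.sum(), (~fa).sum()], [fb.sum(), (~fb).sum()]]
        try:
            _, p = chi_square_test(table)
        except ValueError:
            p = np.nan
        rows.append(_baseline_row(name, 100 * fa.mean(), 100 * fb.mean(), p))
    out = pd.DataFrame(rows)
    out.insert(1, "groups", f"{labels[0]} vs {labels[1]}")
    return out


def run_full_analysis(
    cohort: Union[pd.DataFrame, str, Path], config: RunConfig | None = None
) -> ReportBundle:
    """Run the complete validation analysis over a cohort table.

    Produces per-child scores and outcomes, the test-characteristics table at
    the (constrained) best cut-points, the stratified AUC table (full cohort,
    by examiner type, by age band), baseline comparison tables, clinical
    impression accuracy, ROC point sets, and a manifest with configuration,
    analysis n per scale and exclusion counts.
    """
    config = config or RunConfig()
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    validate_cohort_schema(cohort)

    scored = score_cohort(cohort, eyes_strict=config.who_eyes_strict)
    outcomes = criterion_outcomes(cohort, config)
    per_child = scored.merge(outcomes, on="child_id", validate="1:1")
    per_child["severe_disease_binary"] = _binary_outcome(per_child)

    determinate = per_child[per_child["severe_disease_binary"].notna()].copy()
    if determinate.empty:
        raise ValueError(
            "no child has a determinate severe-disease outcome "
            "(all gaining/losing/single-weight survivors); evaluation is impossible"
        )
    y_all = determinate["severe_disease_binary"].astype(int)
    if y_all.min() == y_all.max():
        raise ValueError("determinate cohort has a single outcome class; evaluation is impossible")

    accuracy_rows, roc_points = [], {}
    for scale_id, col in SCALE_SCORE_COLUMNS.items():
        sub = determinate[determinate[col].notna()]
        y = sub["severe_disease_binary"].astype(int).to_numpy()
        scores = sub[col].to_numpy(float)
        roc = empirical_roc(scores, y)
        roc_points[scale_id] = roc.to_frame()
        if config.cutpoints and scale_id in config.cutpoints:
            cut = config.cutpoints[scale_id]
        else:
            cut = best_cutpoint(roc, config.spec_floor)
        table = ContingencyTable.from_predictions(scores >= cut, y)
        tc = test_characteristics(table)
        accuracy_rows.append(
            {
                "scale": scale_id,
                "cutpoint": cut,
                "n": len(sub),
                "n_pos": tc.n_pos,
                "n_neg": tc.n_neg,
                "auc": roc.auc,
                "auc_ci_lower": roc.ci95[0],
                "auc_ci_upper": roc.ci95[1],
                "sensitivity_pct": 100 * tc.sensitivity,
                "sensitivity_ci_lower": 100 * tc.sensitivity_ci[0],
                "sensitivity_ci_upper": 100 * tc.sensitivity_ci[1],
                "specificity_pct": 100 * tc.specificity,
                "specificity_ci_lower": 100 * tc.specificity_ci[0],
                "specificity_ci_upper": 100 * tc.specificity_ci[1],
                "lr_pos": tc.lr_pos,
                "lr_pos_ci_lower": tc.lr_pos_ci[0] if tc.lr_pos_ci else np.nan,
                "lr_pos_ci_upper": tc.lr_pos_ci[1] if tc.lr_pos_ci else np.nan,
                "lr_neg": tc.lr_neg,
                "lr_neg_ci_lower": tc.lr_neg_ci[0] if tc.lr_neg_ci else np.nan,
                "lr_neg_ci_upper": tc.lr_neg_ci[1] if tc.lr_neg_ci else np.nan,
            }
        )
    accuracy_table = pd.DataFrame(accuracy_rows)

    eval_df = determinate.rename(columns={"severe_disease_binary": "outcome"})
    eval_df["outcome"] = eval_df["outcome"].astype(int)
    strata_frames = [
        subgroup_report(eval_df, split, SCALE_SCORE_COLUMNS, "outcome", config.age_boundary_months)
        for split in ("none", "provider", "age")
    ]
    stratified_auc = pd.concat(strata_frames, ignore_index=True)

    achieved = per_child["weight_status"] == "stable"
    baseline_stable = _compare_groups(
        per_child, achieved, ("achieved_stable_weight", "did_not_achieve")
    )
    nurse = per_child["provider"] == "nurse"
    extra = [
        ("severe_dehydration_pct", per_child["dehydration_category"] == "severe"),
        ("death_pct", per_child["died"] == 1),
    ]
    baseline_provider = _compare_groups(per_child, nurse, ("nurse", "physician"), extra)

    if "clinical_impression_severe" in determinate.columns:
        tc = impression_characteristics(
            determinate["clinical_impression_severe"].to_numpy(int), y_all.to_numpy()
        )
        impression_table = pd.DataFrame(
            [
                {
                    "sensitivity_pct": 100 * tc.sensitivity,
                    "specificity_pct": 100 * tc.specificity,
                    "lr_pos": tc.lr_pos,
                    "lr_pos_ci_lower": tc.lr_pos_ci[0] if tc.lr_pos_ci else np.nan,
                    "lr_pos_ci_upper": tc.lr_pos_ci[1] if tc.lr_pos_ci else np.nan,
                    "lr_neg": tc.lr_neg,
                    "lr_neg_ci_lower": tc.lr_neg_ci[0] if tc.lr_neg_ci else np.nan,
                    "lr_neg_ci_upper": tc.lr_neg_ci[1] if tc.lr_neg_ci else np.nan,
                    "lr_pos_significant": tc.lr_pos_significant(),
                    "lr_neg_significant": tc.lr_neg_significant(),
                }
            ]
        )
    else:
        impression_table = pd.DataFrame()

    status_counts = per_child["weight_status"].value_counts().to_dict()
    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "n_enrolled": int(len(per_child)),
        "n_determinate": int(len(determinate)),
        "n_outcome_positive": int(y_all.sum()),
        "weight_status_counts": {k: int(v) for k, v in status_counts.items()},
        "per_scale_analysis_n": {
            scale: int(determinate[col].notna().sum())
            for scale, col in SCALE_SCORE_COLUMNS.items()
        },
        "per_scale_incomplete": {
            scale: int(per_child[col].isna().sum())
            for scale, col in SCALE_SCORE_COLUMNS.items()
        },
    }
    return ReportBundle(
        per_child=per_child,
        accuracy_table=accuracy_table,
        stratified_auc=stratified_auc,
        baseline_stable=baseline_stable,
        baseline_provider=baseline_provider,
        impression_table=impression_table,
        roc_points=roc_points,
        manifest=manifest,
    )


def write_report(bundle: ReportBundle, outdir: Union[str, Path]) -> list[Path]:
    """Write the report bundle as CSV tables plus a JSON manifest; returns the
    paths written (deterministic given identical inputs and config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    _csv(bundle.per_child, "per_child.csv")
    _csv(bundle.accuracy_table, "accuracy_table.csv")
    _csv(bundle.stratified_auc, "stratified_auc.csv")
    _csv(bundle.baseline_stable, "baseline_stable_weight.csv")
    _csv(bundle.baseline_provider, "baseline_provider.csv")
    _csv(bundle.impression_table, "clinical_impression.csv")
    for scale, df in bundle.roc_points.items():
        _csv(df, f"roc_{scale.lower()}.csv")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
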