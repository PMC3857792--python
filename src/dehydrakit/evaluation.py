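"""Diagnostic-accuracy evaluation: empirical ROC curves, AUC with
Hanley-McNeil confidence intervals, constrained best cut-points, test
characteristics with likelihood-ratio CIs, and the nonparametric baseline
comparison tests (Mann-Whitney U, chi-square).

Conventions
-----------
* Positivity rule is ``score >= threshold`` throughout.
* The AUC equals the Mann-Whitney probability that a random outcome-positive
  child outscores a random outcome-negative child, ties counted half; the
  trapezoidal area under the empirical ROC is identical.
* AUC standard errors follow Hanley & McNeil's formula with
  Q1 = A/(2-A), Q2 = 2A^2/(1+A).
* Proportion CIs are Wald, switching to exact Clopper-Pearson when the
  estimate sits on the 0/1 boundary; LR CIs use the log method.
* No multiple-comparison adjustment is applied anywhere.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ROCCurve",
    "ContingencyTable",
    "TestCharacteristics",
    "empirical_roc",
    "auc_mann_whitney",
    "auc_ci_hanley",
    "is_significant_predictor",
    "best_cutpoint",
    "test_characteristics",
    "lr_from_rates",
    "mann_whitney_test",
    "chi_square_test",
    "subgroup_report",
    "impression_characteristics",
]


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve with AUC and Hanley-McNeil 95% CI.

    ``thresholds`` are ascending; ``sensitivity``/``specificity`` give the
    operating point of the rule ``score >= threshold`` at each, including a
    sentinel threshold above the maximum score so the (0, 1) endpoint is
    present (the minimum threshold yields (1, 0)).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _validate_two_class(outcomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = outcomes == 1
    if not pos.any():
        raise ValueError("no outcome-positive subjects in sample")
    if pos.all():
        raise ValueError("no outcome-negative subjects in sample")
    return pos, ~pos


def auc_mann_whitney(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """AUC as the Mann-Whitney two-sample statistic.

    (# positive-negative pairs where the positive scores higher, plus half
    the tied pairs) / (n_pos * n_neg). Computed via midranks, so ties are
    counted half without enumerating pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    pos, neg = _validate_two_class(y)
    n1, n0 = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_ci_hanley(auc: float, n_pos: int, n_neg: int) -> tuple[float, tuple[float, float]]:
    """Hanley-McNeil standard error and 95% CI for an AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the CI is A +/- 1.96*SE clipped
    to [0, 1]. A degenerate AUC of exactly 0 or 1 yields SE 0 with a warning.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subject in each class")
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc in (0.0, 1.0):
        warnings.warn("degenerate AUC of exactly %g: SE is 0" % auc, stacklevel=2)
        return 0.0, (auc, auc)
    se = math.sqrt(hanley_variance(auc, n_pos, n_neg))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return se, (lo, hi)


def hanley_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil AUC variance (exponential-distribution kernel)."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )


def empirical_roc(scores: Sequence[float], outcomes: Sequence[int]) -> ROCCurve:
    """Empirical ROC over every distinct score threshold.

    One operating point per distinct score value (rule ``score >= t``) plus a
    sentinel above the maximum, so the degenerate endpoints (sens, spec) =
    (1, 0) and (0, 1) always appear. The AUC is the Mann-Whitney value, which
    equals the trapezoidal area under these points.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    pos, neg = _validate_two_class(y)
    n1, n0 = int(pos.sum()), int(neg.sum())
    uniq = np.unique(s)
    thresholds = np.append(uniq, uniq[-1] + 1.0)  # sentinel: nothing positive
    sens = np.array([(s[pos] >= t).mean() for t in thresholds])
    spec = np.array([(s[neg] < t).mean() for t in thresholds])
    auc = auc_mann_whitney(s, y)
    se, ci = auc_ci_hanley(auc, n1, n0)
    return ROCCurve(thresholds, sens, spec, auc, se, ci, n1, n0)


def is_significant_predictor(roc: ROCCurve) -> bool:
    """True when the AUC's 95% CI lies strictly above the 0.5 chance line."""
    return roc.ci95[0] > 0.5


def best_cutpoint(roc: ROCCurve, spec_floor: float = 0.5) -> float:
    """Best cut-point: maximize sensitivity subject to specificity > floor.

    Severe disease must not be missed, so among thresholds keeping
    specificity above ``spec_floor`` the most sensitive one wins; ties go to
    the higher specificity, then to the lower threshold.
    """
    feasible = [
        (roc.sensitivity[i], roc.specificity[i], roc.thresholds[i])
        for i in range(len(roc.thresholds))
        if roc.specificity[i] > spec_floor
    ]
    if not feasible:
        raise ValueError(
            f"no threshold achieves specificity above {spec_floor}; relax the floor"
        )
    best = max(feasible, key=lambda t: (t[0], t[1], -t[2]))
    return float(best[2])


# ---------------------------------------------------------------------------
# 2x2 test characteristics


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for a dichotomized test against the outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_predictions(cls, predicted: Sequence[int], outcomes: Sequence[int]) -> "ContingencyTable":
        p = np.asarray(predicted, dtype=bool)
        y = np.asarray(outcomes, dtype=bool)
        if p.shape != y.shape:
            raise ValueError("predictions and outcomes must have equal length")
        return cls(
            tp=int((p & y).sum()),
            fp=int((p & ~y).sum()),
            fn=int((~p & y).sum()),
            tn=int((~p & ~y).sum()),
        )


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity and likelihood ratios with 95% CIs.

    Undefined quantities (division by zero) are ``None`` with the matching
    ``*_nc`` flag set, mirroring the "NC" (not calculable) convention of
    published accuracy tables. A perfectly sensitive test has LR- = 0.0 with
    an NC interval.
    """

    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    lr_pos: Optional[float]
    lr_neg: Optional[float]
    lr_pos_ci: Optional[tuple[float, float]]
    lr_neg_ci: Optional[tuple[float, float]]
    n_pos: int
    n_neg: int

    @property
    def lr_pos_nc(self) -> bool:
        return self.lr_pos is None

    @property
    def lr_neg_ci_nc(self) -> bool:
        return self.lr_neg_ci is None

    def lr_pos_significant(self) -> Optional[bool]:
        """LR+ CI excludes 1 (a positive result genuinely raises the odds)."""
        if self.lr_pos_ci is None:
            return None
        return self.lr_pos_ci[0] > 1.0 or self.lr_pos_ci[1] < 1.0

    def lr_neg_significant(self) -> Optional[bool]:
        if self.lr_neg_ci is None:
            return None
        return self.lr_neg_ci[0] > 1.0 or self.lr_neg_ci[1] < 1.0


def _proportion_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    # Wald in the interior; exact Clopper-Pearson on the 0/1 boundary where
    # Wald collapses to a point.
    method = "beta" if k in (0, n) else "normal"
    lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
    return float(max(0.0, lo)), float(min(1.0, hi))


def lr_from_rates(sensitivity: float, specificity: float) -> tuple[Optional[float], Optional[float]]:
    """Likelihood ratios from sensitivity and specificity.

    LR+ = se/(1-sp), LR- = (1-se)/sp; a zero denominator yields ``None``
    (reported as NC).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    lr_pos = sensitivity / (1.0 - specificity) if specificity < 1.0 else None
    lr_neg = (1.0 - sensitivity) / specificity if specificity > 0.0 else None
    return lr_pos, lr_neg


def round_lr(value: Optional[float], ndigits: int = 1) -> Optional[float]:
    """Reporting helper: likelihood ratios are printed to one decimal."""
    return None if value is None else round(value, ndigits)


def test_characteristics(table: ContingencyTable, alpha: float = 0.05) -> TestCharacteristics:
    """Sensitivity, specificity and likelihood ratios with 95% CIs from a 2x2.

    LR CIs use the log method: exp(ln LR +/- z * SE(ln LR)) with
    SE(ln LR+)^2 = (1-se)/(se*n_pos) + sp/((1-sp)*n_neg) and the mirrored
    variance for LR-. Boundary estimates (se or sp of 0 or 1) make the
    corresponding LR or its CI not calculable.
    """
    n1, n0 = table.n_pos, table.n_neg
    if n1 < 1 or n0 < 1:
        raise ValueError("need at least one subject in each outcome class")
    se = table.tp / n1
    sp = table.tn / n0
    se_ci = _proportion_ci(table.tp, n1, alpha)
    sp_ci = _proportion_ci(table.tn, n0, alpha)
    lr_pos, lr_neg = lr_from_rates(se, sp)
    z = stats.norm.ppf(1 - alpha / 2)

    # Log-method CIs need the defining cells non-empty; a perfectly sensitive
    # test keeps its LR+ CI (the se term of the variance vanishes) but its
    # LR- of 0 has no calculable interval.
    lr_pos_ci = None
    if lr_pos is not None and table.tp > 0 and table.fp > 0:
        var = (1 - se) / (se * n1) + sp / ((1 - sp) * n0)
        half = z * math.sqrt(var)
        lr_pos_ci = (lr_pos * math.exp(-half), lr_pos * math.exp(half))
    lr_neg_ci = None
    if lr_neg is not None and table.fn > 0 and table.tn > 0:
        var = se / ((1 - se) * n1) + (1 - sp) / (sp * n0)
        half = z * math.sqrt(var)
        lr_neg_ci = (lr_neg * math.exp(-half), lr_neg * math.exp(half))

    return TestCharacteristics(
        sensitivity=se,
        specificity=sp,
        sensitivity_ci=se_ci,
        specificity_ci=sp_ci,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        lr_pos_ci=lr_pos_ci,
        lr_neg_ci=lr_neg_ci,
        n_pos=n1,
        n_neg=n0,
    )


def impression_characteristics(
    impressions: Sequence[int], outcomes: Sequence[int]
) -> TestCharacteristics:
    """Accuracy of the examiner's overall clinical impression of severe
    dehydration, as a binary test against the severe-disease outcome."""
    table = ContingencyTable.from_predictions(impressions, outcomes)
    return test_characteristics(table)


# ---------------------------------------------------------------------------
# Baseline-comparison tests


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1, n = len(x), len(combined)
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return float(u_obs), count / total


def mann_whitney_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for continuous, non-parametric data.

    Exact enumeration of all group assignments for combined n <= 10 (valid
    under ties); otherwise the tie-corrected normal approximation. Returns
    (U statistic of ``x``, p-value).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    if xa.size + ya.size <= 10:
        return _exact_mwu_p(xa, ya)
    if np.unique(np.concatenate([xa, ya])).size == 1:
        return float(xa.size * ya.size / 2.0), 1.0
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", use_continuity=False, method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_test(table: Sequence[Sequence[float]], correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a contingency table (no continuity
    correction by default). Errors on a zero marginal."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    statistic, p, _, expected = stats.chi2_contingency(t, correction=correction)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(statistic), float(p)


# ---------------------------------------------------------------------------
# Subgroups


def subgroup_report(
    cohort: pd.DataFrame,
    split: str,
    score_columns: Mapping[str, str],
    outcome_column: str = "severe_disease",
    age_boundary_months: float = 12.0,
) -> pd.DataFrame:
    """Stratified AUC table (one row per scale per stratum).

    ``split`` is ``"provider"`` (nurse vs physician strata from the
    ``provider`` column), ``"age"`` (under vs over ``age_boundary_months``;
    a child exactly at the boundary goes to the older stratum), or
    ``"none"`` (full cohort only). Strata missing an outcome class are
    flagged, not computed. Rows carry AUC, Hanley 95% CI, class sizes and a
    significance flag (CI lower bound above 0.5).
    """
    if split == "provider":
        strata = {
            "nurse": cohort["provider"] == "nurse",
            "physician": cohort["provider"] == "physician",
        }
    elif split == "age":
        under = cohort["age_months"] < age_boundary_months
        strata = {
            f"under_{age_boundary_months:g}m": under,
            f"over_{age_boundary_months:g}m": ~under,
        }
    elif split == "none":
        strata = {"full_cohort": pd.Series(True, index=cohort.index)}
    else:
        raise ValueError(f"unknown split {split!r}")

    rows = []
    for stratum, mask in strata.items():
        sub = cohort[mask]
        for scale_id, col in score_columns.items():
            valid = sub[col].notna() & sub[outcome_column].notna()
            scores = sub.loc[valid, col].to_numpy(dtype=float)
            y = sub.loc[valid, outcome_column].to_numpy(dtype=int)
            row = {"stratum": stratum, "scale": scale_id, "n": int(valid.sum())}
            if y.size == 0 or y.min() == y.max():
                row.update(
                    auc=np.nan, se=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                    n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()),
                    significant=None, flag="single-outcome-class",
                )
            else:
                roc = empirical_roc(scores, y)
                row.update(
                    auc=roc.auc, se=roc.se, ci_lower=roc.ci95[0], ci_upper=roc.ci95[1],
                    n_pos=roc.n_pos, n_neg=roc.n_neg,
                    significant=is_significant_predictor(roc), flag="",
                )
            rows.append(row)
    return pd.DataFrame(rows)
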