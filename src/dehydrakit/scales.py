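"""Clinical dehydration scales: WHO severe dehydration scale, CDC scale, and
the Clinical Dehydration Scale (CDS).

All three scales are derived from one canonical set of ordinal clinical-sign
observations per child. The twelve CDC items are recorded on a three-level
ordinal scale (0/1/2 points); the four WHO items are binary (0/1 point each,
severe dehydration at >= 2 points total); the CDS is a four-item, 8-point
scale built from a subset of the same signs.

Point assignments live in ``data/scale_definitions.json`` so the maps are
data, not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

CDC_ITEMS: tuple[str, ...] = (
    "mental_status",
    "thirst",
    "heart_rate",
    "pulse_quality",
    "breathing",
    "eyes",
    "tears",
    "mouth_tongue",
    "skin_recoil",
    "capillary_refill",
    "extremities",
    "urine_output",
)

WHO_ITEMS: tuple[str, ...] = ("who_mental", "who_eyes", "who_thirst", "who_skin_pinch")


def load_scale_definitions() -> dict:
    """Load the machine-readable scale definitions (point maps as data)."""
    with resources.files("dehydrakit.data").joinpath("scale_definitions.json").open() as fh:
        return json.load(fh)


_DEFS = load_scale_definitions()


class IncompleteScoreError(ValueError):
    """Raised when an operation requires a complete score but got an incomplete one."""


@dataclass(frozen=True)
class ObservationSet:
    """One child's canonical ordinal clinical-sign recordings.

    The twelve CDC items take levels 0 (column 1), 1 (column 2), 2 (column 3);
    ``None`` marks a missing recording. The four ``who_*`` fields hold direct
    binary WHO recordings when the examiner charted the WHO items separately;
    when absent the WHO items are derived from the CDC items.
    """

    mental_status: Optional[int] = None
    thirst: Optional[int] = None
    heart_rate: Optional[int] = None
    pulse_quality: Optional[int] = None
    breathing: Optional[int] = None
    eyes: Optional[int] = None
    tears: Optional[int] = None
    mouth_tongue: Optional[int] = None
    skin_recoil: Optional[int] = None
    capillary_refill: Optional[int] = None
    extremities: Optional[int] = None
    urine_output: Optional[int] = None
    who_mental: Optional[int] = None
    who_eyes: Optional[int] = None
    who_thirst: Optional[int] = None
    who_skin_pinch: Optional[int] = None

    def __post_init__(self) -> None:
        for item in CDC_ITEMS:
            v = getattr(self, item)
            if v is not None and v not in (0, 1, 2):
                raise ValueError(f"{item}={v!r}: CDC sign levels must be 0, 1 or 2")
        for item in WHO_ITEMS:
            v = getattr(self, item)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{item}={v!r}: WHO sign recordings must be 0 or 1")

    @property
    def cdc_complete(self) -> bool:
        return all(getattr(self, item) is not None for item in CDC_ITEMS)

    def missing_cdc_items(self) -> list[str]:
        return [item for item in CDC_ITEMS if getattr(self, item) is None]


@dataclass(frozen=True)
class ScaleScore:
    """Points on one scale, with an explicit completeness flag.

    Incomplete scores (missing constituent signs) carry ``complete=False`` and
    ``points=None``; downstream accuracy analyses exclude them per scale rather
    than imputing.
    """

    scale_id: str
    points: Optional[int]
    max_points: int
    complete: bool = True
    missing: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.complete:
            if self.points is None or not (0 <= self.points <= self.max_points):
                raise ValueError(
                    f"{self.scale_id} points {self.points} outside [0, {self.max_points}]"
                )
        elif self.points is not None:
            raise ValueError("incomplete scores carry no point total")


def _resolve_who_item(obs: ObservationSet, who_item: str, *, prefer_direct: bool,
                      eyes_strict: bool) -> Optional[int]:
    direct = getattr(obs, who_item)
    if direct is not None and prefer_direct:
        return direct
    spec = _DEFS["who"]["derive_from_cdc"][who_item]
    cdc_val = getattr(obs, spec["cdc_item"])
    if cdc_val is None:
        return direct  # may still be None -> unresolvable
    key = "strict_positive_levels" if (eyes_strict and "strict_positive_levels" in spec) else "positive_levels"
    return 1 if cdc_val in spec[key] else 0


def score_who(obs: ObservationSet, prefer_direct: bool = True, *,
              eyes_strict: bool = False) -> ScaleScore:
    """Score the 4-item WHO severe dehydration scale (0-4 points).

    Each item contributes 1 point at its severe level. Direct WHO recordings
    are used when present and ``prefer_direct`` is set; otherwise items are
    derived from the CDC signs: lethargic/unconscious mental status -> 1;
    sunken eyes (any degree; only "very sunken" if ``eyes_strict``) -> 1;
    unable to drink -> 1; skin recoil > 2 s -> 1.
    """
    values, missing = {}, []
    for item in WHO_ITEMS:
        v = _resolve_who_item(obs, item, prefer_direct=prefer_direct, eyes_strict=eyes_strict)
        if v is None:
            missing.append(item)
        else:
            values[item] = v
    if missing:
        return ScaleScore("WHO", None, 4, complete=False, missing=tuple(missing))
    return ScaleScore("WHO", sum(values.values()), 4)


def score_cdc(obs: ObservationSet) -> ScaleScore:
    """Score the 12-item CDC scale: sum of ordinal levels, range 0-24."""
    missing = obs.missing_cdc_items()
    if missing:
        return ScaleScore("CDC", None, 24, complete=False, missing=tuple(missing))
    return ScaleScore("CDC", sum(getattr(obs, item) for item in CDC_ITEMS), 24)


def cds_general_appearance(mental_status: int, thirst: int) -> int:
    """CDS "general appearance" from mental status and thirst.

    Level 2 = lethargic or unconscious; level 1 = thirsty, restless, or
    irritable (restless/irritable mental status, or any abnormal thirst);
    level 0 = normal.
    """
    if mental_status == 2:
        return 2
    if mental_status == 1 or thirst >= 1:
        return 1
    return 0


def score_cds(obs: ObservationSet) -> ScaleScore:
    """Score the 8-point Clinical Dehydration Scale.

    General appearance (from mental status and thirst) + eyes + mucous
    membranes (mouth and tongue) + tears, each 0-2.
    """
    needed = ("mental_status", "thirst", "eyes", "mouth_tongue", "tears")
    missing = [item for item in needed if getattr(obs, item) is None]
    if missing:
        return ScaleScore("CDS", None, 8, complete=False, missing=tuple(missing))
    points = (
        cds_general_appearance(obs.mental_status, obs.thirst)
        + obs.eyes
        + obs.mouth_tongue
        + obs.tears
    )
    return ScaleScore("CDS", points, 8)


def classify(score: ScaleScore, cutpoint: int) -> bool:
    """Dichotomize a complete scale score: positive iff points >= cutpoint."""
    if not score.complete:
        raise IncompleteScoreError(
            f"cannot classify incomplete {score.scale_id} score (missing: {', '.join(score.missing)})"
        )
    return score.points >= cutpoint


SCORERS = {"WHO": score_who, "CDC": score_cdc, "CDS": score_cds}

#: Best cut-points for severe disease reported for each scale.
DEFAULT_CUTPOINTS = {"WHO": 2, "CDC": 10, "CDS": 4}
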