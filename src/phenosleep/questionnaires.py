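"""Scoring and categorization of the nine self-report instruments.

All instruments are scored as plain sums of item ratings. Severity /
risk categorizations follow each instrument's published cutoffs:

===========  =====  =========  ============  ======================================
Instrument   Items  Item range Total range    Categorization
===========  =====  =========  ============  ======================================
ISI            7      0-4        0-28        none / mild / moderate / severe
IRLS          10      0-4        0-40        mild / moderate / severe / most severe
DBAS          16      0-10       0-160       (continuous only)
STAI-S        20      1-4        20-80       (continuous only)
PHQ-9          9      0-3        0-27        normal / mild / moderate / severe
GAD-7          7      0-3        0-21        normal / mild / moderate / severe
AUDIT-C        3      0-4        0-12        nonhazardous / hazardous (sex cutoff)
SOS-Q         28      1-4        28-112      low risk / high risk (cutoff 49)
BRIAN         21      1-4        18-72*      (continuous only)
===========  =====  =========  ============  ======================================

*BRIAN responses carry 21 items but only the first 18 (the four
rhythm-disturbance categories: sleep, social rhythms, activity, eating)
enter the total; the remaining 3 items collect chronotype information
and are not scored, hence the 18-72 total range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class Instrument(str, Enum):
    ISI = "ISI"
    IRLS = "IRLS"
    DBAS = "DBAS"
    STAI_S = "STAI_S"
    PHQ9 = "PHQ9"
    GAD7 = "GAD7"
    AUDIT_C = "AUDIT_C"
    SOS_Q = "SOS_Q"
    BRIAN = "BRIAN"


@dataclass(frozen=True)
class InstrumentSpec:
    n_items: int
    item_min: int
    item_max: int
    #: number of leading items that enter the total (defaults to all)
    n_scored: int | None = None

    @property
    def scored_items(self) -> int:
        return self.n_scored if self.n_scored is not None else self.n_items

    @property
    def total_min(self) -> int:
        return self.scored_items * self.item_min

    @property
    def total_max(self) -> int:
        return self.scored_items * self.item_max


INSTRUMENTS: dict[Instrument, InstrumentSpec] = {
    Instrument.ISI: InstrumentSpec(7, 0, 4),
    Instrument.IRLS: InstrumentSpec(10, 0, 4),
    Instrument.DBAS: InstrumentSpec(16, 0, 10),
    Instrument.STAI_S: InstrumentSpec(20, 1, 4),
    Instrument.PHQ9: InstrumentSpec(9, 0, 3),
    Instrument.GAD7: InstrumentSpec(7, 0, 3),
    Instrument.AUDIT_C: InstrumentSpec(3, 0, 4),
    Instrument.SOS_Q: InstrumentSpec(28, 1, 4),
    # 21 items; the 3 chronotype items are informational and unscored
    Instrument.BRIAN: InstrumentSpec(21, 1, 4, n_scored=18),
}


class ValidationError(ValueError):
    """Raised when a response violates its instrument's item contract."""


@dataclass(frozen=True)
class QuestionnaireResponse:
    instrument: Instrument
    items: tuple[int, ...]
    respondent_sex: str | None = None  # "male"/"female"; required by AUDIT-C cutoff

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(int(i) for i in self.items))
        spec = INSTRUMENTS[Instrument(self.instrument)]
        if len(self.items) != spec.n_items:
            raise ValidationError(
                f"{self.instrument}: expected {spec.n_items} items, got {len(self.items)}"
            )
        for idx, rating in enumerate(self.items):
            if not (spec.item_min <= rating <= spec.item_max):
                raise ValidationError(
                    f"{self.instrument}: item {idx} rating {rating} outside "
                    f"[{spec.item_min}, {spec.item_max}]"
                )


@dataclass(frozen=True)
class ScoredScale:
    instrument: Instrument
    total: int
    category: str | None = None


def score(response: QuestionnaireResponse) -> ScoredScale:
    """Sum item ratings into the instrument total and attach its category.

    Totals are unweighted sums (no instrument here reverse-scores items).
    BRIAN sums only its 18 scored items. The category is the instrument's
    published severity/risk band where one exists, else ``None``.
    """
    instrument = Instrument(response.instrument)
    spec = INSTRUMENTS[instrument]
    total = sum(response.items[: spec.scored_items])
    if not (spec.total_min <= total <= spec.total_max):  # pragma: no cover
        raise ValidationError(f"{instrument}: total {total} outside printed range")
    category: str | None
    if instrument is Instrument.ISI:
        category = classify_isi(total)
    elif instrument is Instrument.IRLS:
        category = classify_irls(total)
    elif instrument is Instrument.PHQ9:
        category = classify_phq9(total)
    elif instrument is Instrument.GAD7:
        category = classify_gad7(total)
    elif instrument is Instrument.AUDIT_C:
        if response.respondent_sex is None:
            category = None
        else:
            category = classify_auditc(total, response.respondent_sex)
    elif instrument is Instrument.SOS_Q:
        category = classify_sosq(total)
    else:
        category = None
    return ScoredScale(instrument=instrument, total=total, category=category)


def _check_range(total: int, lo: int, hi: int, name: str) -> None:
    if not (lo <= total <= hi):
        raise ValidationError(f"{name} total {total} outside [{lo}, {hi}]")


ISI_BANDS = ((0, 7, "no_insomnia"), (8, 14, "mild"), (15, 21, "moderate"), (22, 28, "severe"))


def classify_isi(total: int) -> str:
    """Band an ISI total: 0-7 none, 8-14 mild, 15-21 moderate, 22-28 severe."""
    _check_range(total, 0, 28, "ISI")
    for lo, hi, label in ISI_BANDS:
        if lo <= total <= hi:
            return label
    raise AssertionError("unreachable")


def classify_irls(total: int) -> str:
    """Band an IRLS total: 0-10 mild, 11-20 moderate, 21-30 severe, 31-40 most severe."""
    _check_range(total, 0, 40, "IRLS")
    if total <= 10:
        return "mild"
    if total <= 20:
        return "moderate"
    if total <= 30:
        return "severe"
    return "most_severe"


def classify_phq9(total: int) -> str:
    """Band a PHQ-9 total: 0-4 normal, 5-9 mild, 10-19 moderate, 20-27 severe."""
    _check_range(total, 0, 27, "PHQ-9")
    if total <= 4:
        return "normal"
    if total <= 9:
        return "mild"
    if total <= 19:
        return "moderate"
    return "severe"


def classify_gad7(total: int) -> str:
    """Band a GAD-7 total: 0-4 normal, 5-9 mild, 10-14 moderate, 15-21 severe."""
    _check_range(total, 0, 21, "GAD-7")
    if total <= 4:
        return "normal"
    if total <= 9:
        return "mild"
    if total <= 14:
        return "moderate"
    return "severe"


def classify_auditc(total: int, sex: str) -> str:
    """AUDIT-C hazardous-drinking screen: cutoff >=4 for men, >=3 for women."""
    _check_range(total, 0, 12, "AUDIT-C")
    if sex not in ("male", "female"):
        raise ValidationError(f"AUDIT-C classification requires sex male/female, got {sex!r}")
    cutoff = 4 if sex == "male" else 3
    return "hazardous" if total >= cutoff else "nonhazardous"


def classify_sosq(total: int) -> str:
    """SOS-Q smartphone-overuse risk: strictly above 49 is high risk.

    A total of exactly 49 is assigned low risk (the published cutoff
    sentence reads "scores higher than 49 indicate a high risk").
    """
    _check_range(total, 28, 112, "SOS-Q")
    return "high_risk" if total > 49 else "low_risk"


def screen_eligibility(
    isi_total: int,
    weekly_symptom_days: int,
    exclusion_flags: Sequence[str] = (),
) -> str:
    """Apply the enrollment screen.

    The screening ISI administration uses stricter bands than the
    analysis grouping: insomnia arm requires ISI > 15 with symptoms on
    >= 3 days/week; no-insomnia arm requires ISI < 8 with symptoms on
    < 3 days/week; anyone else (including the 8-15 gap) is ineligible,
    as is anyone carrying an exclusion flag.
    """
    if exclusion_flags:
        return "ineligible"
    if isi_total > 15 and weekly_symptom_days >= 3:
        return "insomnia_arm"
    if isi_total < 8 and weekly_symptom_days < 3:
        return "no_insomnia_arm"
    return "ineligible"
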