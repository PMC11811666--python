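"""Time-of-day-weighted encoding of daily EMA self-reports.

Each daily ecological momentary assessment (EMA) entry records one of
four behaviors — caffeine intake, alcohol consumption, a nap, or a
stress episode — together with when in the day it occurred (morning,
afternoon, or before bedtime). Entries are turned into numbers in two
steps: a kind-specific encoding (reported amount for caffeine/alcohol;
an ordinal code for nap duration and stress intensity), then a
multiplicative time-of-day weight reflecting how disruptive to sleep
the behavior is at that time. Late-day caffeine, naps, and stress are
weighted more heavily than earlier occurrences; for alcohol, morning
drinking is weighted above afternoon drinking (morning drinking being
the more harmful pattern) with before-bedtime drinking weighted highest.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping

KINDS = ("caffeine", "alcohol", "nap", "stress")
SLOTS = ("morning", "afternoon", "before_bedtime")
NAP_CATEGORIES = ("<1h", "1-2h", "2-3h", ">3h")
STRESS_INTENSITIES = ("mild", "moderate", "severe")

#: multiplicative (kind, slot) weights for morning / afternoon / before bedtime
DEFAULT_WEIGHTS: Mapping[str, tuple[float, float, float]] = {
    "caffeine": (1.0, 1.5, 2.0),
    "nap": (1.0, 1.5, 2.0),
    "stress": (1.0, 1.5, 2.0),
    "alcohol": (1.5, 1.0, 2.0),
}

# Ordinal encodings. Nap categories are half-open duration intervals
# [0,1), [1,2), [2,3), [3,inf) hours.
_NAP_CODE = {"<1h": 0.5, "1-2h": 1.0, "2-3h": 2.0, ">3h": 3.0}
_STRESS_CODE = {"mild": 1.0, "moderate": 2.0, "severe": 3.0}


class EMAError(ValueError):
    """Raised for entries outside the legal kind/slot/category enumerations."""


@dataclass(frozen=True)
class EMAEntry:
    """One dated self-report event.

    ``magnitude`` is the self-reported amount (unitless count: cups,
    standard drinks) for caffeine and alcohol, and the duration/intensity
    category string for nap and stress.
    """

    participant_id: str
    date: Date
    kind: str
    slot: str
    magnitude: float | str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise EMAError(f"unknown EMA kind {self.kind!r}")
        if self.slot not in SLOTS:
            raise EMAError(f"unknown time-of-day slot {self.slot!r}")
        if self.kind in ("caffeine", "alcohol"):
            mag = float(self.magnitude)
            if mag < 0:
                raise EMAError(f"{self.kind} amount must be >= 0, got {mag}")
        elif self.kind == "nap" and self.magnitude not in NAP_CATEGORIES:
            raise EMAError(f"unknown nap duration category {self.magnitude!r}")
        elif self.kind == "stress" and self.magnitude not in STRESS_INTENSITIES:
            raise EMAError(f"unknown stress intensity {self.magnitude!r}")


def encode_nap(category: str) -> float:
    """Encode a nap duration category: <1h → 0.5, 1-2h → 1, 2-3h → 2, >3h → 3."""
    try:
        return _NAP_CODE[category]
    except KeyError:
        raise EMAError(f"unknown nap duration category {category!r}") from None


def encode_stress(intensity: str) -> float:
    """Encode stress intensity: mild → 1, moderate → 2, severe → 3."""
    try:
        return _STRESS_CODE[intensity]
    except KeyError:
        raise EMAError(f"unknown stress intensity {intensity!r}") from None


def _encoded_magnitude(entry: EMAEntry) -> float:
    if entry.kind == "nap":
        return encode_nap(str(entry.magnitude))
    if entry.kind == "stress":
        return encode_stress(str(entry.magnitude))
    return float(entry.magnitude)


def weighted_value(
    entry: EMAEntry, weights: Mapping[str, tuple[float, float, float]] = DEFAULT_WEIGHTS
) -> float:
    """Encoded magnitude times the (kind, slot) time-of-day weight."""
    slot_index = SLOTS.index(entry.slot)
    return _encoded_magnitude(entry) * weights[entry.kind][slot_index]


def aggregate_participant(
    entries: Iterable[EMAEntry],
    weights: Mapping[str, tuple[float, float, float]] = DEFAULT_WEIGHTS,
    study_days: int = 28,
    statistic: str = "sum",
) -> dict[str, float]:
    """Collapse one participant's EMA log to a per-kind summary value.

    Weighted values are summed within each day, then combined across the
    study period — by default the sum over all days (``statistic="sum"``),
    optionally the mean per day (``statistic="mean_per_day"``, divisor
    ``study_days``). Days with no entry contribute 0. Returns a value for
    every kind, 0 for kinds never reported.
    """
    if statistic not in ("sum", "mean_per_day"):
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    entries = list(entries)
    pids = {e.participant_id for e in entries}
    if len(pids) > 1:
        raise EMAError(f"entries span multiple participants: {sorted(pids)}")
    daily: dict[str, defaultdict[Date, float]] = {k: defaultdict(float) for k in KINDS}
    for entry in entries:
        daily[entry.kind][entry.date] += weighted_value(entry, weights)
    out: dict[str, float] = {}
    for kind in KINDS:
        total = sum(daily[kind].values())
        out[kind] = total / study_days if statistic == "mean_per_day" else total
    return out
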