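"""Per-night and per-participant objective sleep parameters.

The wearable exports one record per night: the total inactive period,
the awake time within it, stage durations (REM / light / deep), and the
number of awakenings. Total sleep time (TST) is the inactive period
minus the awake time. Sleep quality is the percentage of the inactive
period actually spent asleep, 100 x TST / (TST + awake) — i.e. sleep
efficiency over the detected rest interval, which lands on the 80-85%
scale typical of consumer devices.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Sequence


class SleepValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SleepNight:
    participant_id: str
    date: Date
    total_inactive_min: float
    total_awake_min: float
    rem_min: float
    light_min: float
    deep_min: float
    n_wakeups: int

    def __post_init__(self) -> None:
        for name in ("total_inactive_min", "total_awake_min", "rem_min", "light_min", "deep_min"):
            if getattr(self, name) < 0:
                raise SleepValidationError(f"{name} must be >= 0")
        if self.n_wakeups < 0:
            raise SleepValidationError("n_wakeups must be >= 0")
        if self.total_awake_min > self.total_inactive_min:
            raise SleepValidationError("awake time exceeds inactive time")
        staged = self.rem_min + self.light_min + self.deep_min
        if staged > self.total_inactive_min - self.total_awake_min + 1e-9:
            raise SleepValidationError("staged sleep exceeds total sleep time")


@dataclass(frozen=True)
class ParticipantSleepSummary:
    participant_id: str
    n_nights: int
    tst_min: float
    awake_min: float
    rem_min: float
    light_min: float
    deep_min: float
    wakeups_per_week: float
    sleep_quality_pct: float
    n_excluded_nights: int = 0


def total_sleep_time(night: SleepNight) -> float:
    """Minutes asleep: total inactive time minus total awake time."""
    return night.total_inactive_min - night.total_awake_min


def sleep_quality(tst: float, awake: float) -> float:
    """Percentage of the inactive period spent asleep: 100 x TST/(TST+awake)."""
    if tst < 0 or awake < 0:
        raise SleepValidationError("durations must be >= 0")
    if tst + awake == 0:
        raise SleepValidationError("sleep quality undefined for a zero-length night")
    return 100.0 * tst / (tst + awake)


def wakeups_per_week(nights: Sequence[SleepNight]) -> float:
    """Average awakenings scaled to a 7-night week."""
    if not nights:
        raise SleepValidationError("no nights recorded")
    return sum(n.n_wakeups for n in nights) * 7.0 / len(nights)


def summarize_participant(
    nights: Iterable[SleepNight], quality_mode: str = "aggregated"
) -> ParticipantSleepSummary:
    """Average nightly parameters over the recording period.

    Nights with zero inactive time (device non-wear) are excluded and
    counted; the divisor is the number of retained nights. Sleep quality
    is computed from the mean TST and mean awake time by default
    (``quality_mode="aggregated"``); ``"nightly"`` instead averages the
    per-night percentages.
    """
    if quality_mode not in ("aggregated", "nightly"):
        raise ValueError(f"unknown quality_mode {quality_mode!r}")
    all_nights = list(nights)
    kept = [n for n in all_nights if n.total_inactive_min > 0]
    if not kept:
        raise SleepValidationError("no valid nights to summarize")
    pid = kept[0].participant_id
    k = len(kept)
    mean_tst = sum(total_sleep_time(n) for n in kept) / k
    mean_awake = sum(n.total_awake_min for n in kept) / k
    if quality_mode == "aggregated":
        quality = sleep_quality(mean_tst, mean_awake)
    else:
        quality = sum(sleep_quality(total_sleep_time(n), n.total_awake_min) for n in kept) / k
    return ParticipantSleepSummary(
        participant_id=pid,
        n_nights=k,
        tst_min=mean_tst,
        awake_min=mean_awake,
        rem_min=sum(n.rem_min for n in kept) / k,
        light_min=sum(n.light_min for n in kept) / k,
        deep_min=sum(n.deep_min for n in kept) / k,
        wakeups_per_week=wakeups_per_week(kept),
        sleep_quality_pct=quality,
        n_excluded_nights=len(all_nights) - k,
    )
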