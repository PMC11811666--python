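"""Synthetic digital-phenotyping cohort generator.

Generates a full study — participants with ISI severity groups, item-level
questionnaire responses, daily EMA logs, nightly sleep records, and
wearable-style heart-rate and cumulative-step streams — with the
statistical structure the study design calls for:

* four ISI severity groups (none / mild / moderate / severe) at
  configurable proportions, defaulting to 25.2 / 42.4 / 27.6 / 4.8% so a
  250-participant cohort splits 63 / 106 / 69 / 12;
* objective sleep parameters drawn from the SAME distributions for all
  groups (the subjective-objective discrepancy: severity groups do not
  differ in measured sleep);
* psychological scale totals stochastically increasing with severity
  (DBAS, IRLS, STAI-S, PHQ-9, GAD-7, SOS-Q, BRIAN and EMA stress),
  while AUDIT-C, caffeine and alcohol stay group-invariant;
* a heart-rate circadian cosine per participant (MESOR ~74.6 bpm,
  amplitude ~11 bpm, mid-afternoon acrophase) with Gaussian noise, and
  cumulative step counters with a diurnal activity rhythm and log-normal
  increment noise.

All randomness derives from ``CohortConfig.seed`` through per-participant,
per-stream ``numpy.random.SeedSequence`` children, so identical configs
produce identical cohorts regardless of which streams are generated.
The per-participant ground truth (:class:`SyntheticTruth`) is carried
alongside the data for recovery tests only and is never read by the
analysis modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date, datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circadian import EpochSeries
from .questionnaires import INSTRUMENTS, Instrument

GROUPS = ("no_insomnia", "mild", "moderate", "severe")
ISI_BAND = {"no_insomnia": (0, 7), "mild": (8, 14), "moderate": (15, 21), "severe": (22, 28)}

#: per-variable location shifts by group, relative to the no-insomnia
#: baseline; defaults emulate the severity gradients of the observed
#: cohort for the psychological scales and EMA stress, with null effects
#: everywhere else (objective sleep, AUDIT-C, caffeine, alcohol).
DEFAULT_EFFECT_PROFILE: Mapping[str, tuple[float, float, float, float]] = {
    "IRLS": (0.0, 4.0, 9.0, 12.5),
    "DBAS": (0.0, 16.06, 28.95, 54.33),
    "STAI_S": (0.0, 11.0, 15.0, 26.0),
    "PHQ9": (0.0, 3.0, 6.0, 11.5),
    "GAD7": (0.0, 2.0, 3.0, 11.0),
    "SOS_Q": (0.0, 3.0, 10.0, 21.0),
    "BRIAN": (0.0, 9.0, 15.0, 18.0),
    "AUDIT_C": (0.0, 0.0, 0.0, 0.0),
    "stress_rate": (0.0, 0.20, 0.16, 0.45),
    "age": (0.0, 3.0, 3.0, 4.0),
}

# (baseline mean, between-subject SD) of each scale total in the
# no-insomnia group; group means add the effect-profile shift.
_SCALE_BASELINES: Mapping[str, tuple[float, float]] = {
    "IRLS": (1.0, 6.0),
    "DBAS": (65.17, 23.56),
    "STAI_S": (32.0, 10.0),
    "PHQ9": (2.5, 3.5),
    "GAD7": (1.0, 3.0),
    "AUDIT_C": (4.0, 2.5),
    "SOS_Q": (45.0, 13.0),
    "BRIAN": (34.0, 7.0),
}

_SLOTS = ("morning", "afternoon", "before_bedtime")
_NAP_CATS = ("<1h", "1-2h", "2-3h", ">3h")
_STRESS_LEVELS = ("mild", "moderate", "severe")

ALL_STREAMS = ("questionnaires", "ema", "sleep", "heart_rate", "steps")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 250
    group_proportions: tuple[float, float, float, float] = (0.252, 0.424, 0.276, 0.048)
    study_days: int = 28
    hr_epoch_minutes: int = 5
    seed: int = 0
    start_date: Date = Date(2023, 3, 6)  # a Monday
    missing_fraction: float = 0.02
    hr_noise_sd: float = 5.0
    effect_profile: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILE)
    )
    # sleep-night baselines (minutes), identical for every group
    tst_mean: float = 375.5
    tst_between_sd: float = 30.0
    tst_night_sd: float = 25.0
    awake_mean: float = 65.0
    awake_between_sd: float = 9.0
    awake_night_sd: float = 8.0
    stage_means: tuple[float, float, float] = (210.0, 78.0, 54.0)  # REM, light, deep
    wakeups_per_night: float = 3.7

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if len(self.group_proportions) != 4 or any(p < 0 for p in self.group_proportions):
            raise ConfigurationError("group_proportions must be 4 nonnegative fractions")
        if abs(sum(self.group_proportions) - 1.0) > 1e-12:
            raise ConfigurationError("group_proportions must sum to 1")
        if self.study_days < 2:
            raise ConfigurationError("study_days must be >= 2 (cosinor window needs 2 days)")
        if self.hr_epoch_minutes <= 0 or 1440 % self.hr_epoch_minutes != 0:
            raise ConfigurationError("hr_epoch_minutes must divide 1440")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ConfigurationError("missing_fraction must be in [0, 1)")

    def shifts(self, variable: str) -> tuple[float, float, float, float]:
        return tuple(self.effect_profile.get(variable, (0.0, 0.0, 0.0, 0.0)))


@dataclass(frozen=True)
class ParticipantTruth:
    participant_id: str
    index: int
    group: str
    sex: str
    age: int
    isi_screening_total: int
    # circadian ground truth
    hr_mesor: float
    hr_amplitude: float
    hr_acrophase_hours: float
    step_day_rate: float  # mean increment per epoch during the active day
    step_night_rate: float
    # per-kind daily EMA probabilities
    ema_rates: Mapping[str, float]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator-side ground truth; for recovery tests only.

    Never imported by the analysis modules.
    """

    config: CohortConfig
    participants: tuple[ParticipantTruth, ...]
    scale_group_means: Mapping[str, tuple[float, float, float, float]]


@dataclass
class Cohort:
    config: CohortConfig
    truth: SyntheticTruth
    participants: pd.DataFrame
    questionnaires: pd.DataFrame | None = None
    ema: pd.DataFrame | None = None
    sleep: pd.DataFrame | None = None
    heart_rate: dict[str, EpochSeries] | None = None
    steps: dict[str, EpochSeries] | None = None


def _rng(config: CohortConfig, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + path))


def apportion_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n participants to groups."""
    quotas = [p * n for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _compose_items(totals: np.ndarray, n_items: int, item_min: int, item_max: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Distribute integer totals over items within [item_min, item_max].

    Sequential constrained draws, vectorized over respondents: item j is
    uniform on the range that keeps the remaining total feasible.
    """
    totals = totals.astype(int)
    out = np.empty((len(totals), n_items), dtype=int)
    remaining = totals.copy()
    for j in range(n_items):
        left = n_items - j - 1
        lo = np.maximum(item_min, remaining - item_max * left)
        hi = np.minimum(item_max, remaining - item_min * left)
        draw = rng.integers(lo, hi + 1)
        out[:, j] = draw
        remaining -= draw
    return out


def _generate_participants(config: CohortConfig) -> tuple[pd.DataFrame, tuple[ParticipantTruth, ...]]:
    counts = apportion_counts(config.group_proportions, config.n_participants)
    groups: list[str] = []
    for g, c in zip(GROUPS, counts):
        groups.extend([g] * c)
    rng = _rng(config, 0)
    order = rng.permutation(config.n_participants)
    groups = [groups[i] for i in order]
    width = len(str(config.n_participants))
    truths = []
    rows = []
    stress_shifts = config.shifts("stress_rate")
    age_shifts = config.shifts("age")
    for i, group in enumerate(groups):
        g = GROUPS.index(group)
        prng = _rng(config, 1, i)
        pid = f"P{i + 1:0{width}d}"
        sex = "female" if prng.random() < 0.655 else "male"
        age = int(np.clip(round(19 + prng.gamma(2.0, 4.0) + age_shifts[g]), 19, 70))
        if group == "no_insomnia":
            screening = int(prng.integers(0, 8))
        else:
            screening = int(prng.integers(16, 29))
        truth = ParticipantTruth(
            participant_id=pid, index=i, group=group, sex=sex, age=age,
            isi_screening_total=screening,
            hr_mesor=float(prng.normal(74.6, 6.0)),
            hr_amplitude=float(np.clip(prng.normal(11.0, 3.0), 0.5, None)),
            hr_acrophase_hours=float(prng.normal(15.0, 1.5) % 24.0),
            step_day_rate=float(np.clip(prng.normal(55.0, 18.0), 5.0, None)),
            step_night_rate=float(np.clip(prng.normal(2.0, 1.0), 0.1, None)),
            ema_rates={
                "caffeine": 0.30,
                "alcohol": 0.12,
                "nap": 0.15,
                "stress": float(np.clip(0.08 + stress_shifts[g], 0.0, 0.95)),
            },
        )
        truths.append(truth)
        rows.append({
            "participant_id": pid, "group_true": group, "sex": sex, "age": age,
            "isi_screening_total": screening,
        })
    return pd.DataFrame(rows), tuple(truths)


def generate_questionnaires(config: CohortConfig,
                            truths: Sequence[ParticipantTruth]) -> pd.DataFrame:
    """Item-level responses for all nine instruments.

    ISI totals are drawn uniformly inside each participant's group band
    (so the ISI grouping always recovers the assigned group); other
    scale totals are Gaussian around the baseline plus the group's
    effect-profile shift, rounded and clipped to the instrument's legal
    total range, then distributed over items by constrained draws.
    """
    rng = _rng(config, 2)
    group_idx = np.array([GROUPS.index(t.group) for t in truths])
    pids = [t.participant_id for t in truths]
    sexes = [t.sex for t in truths]
    n = len(truths)
    frames = []

    def _emit(name: str, items: np.ndarray) -> None:
        n_items = items.shape[1]
        frames.append(pd.DataFrame({
            "participant_id": np.repeat(pids, n_items),
            "sex": np.repeat(sexes, n_items),
            "instrument": name,
            "item_index": np.tile(np.arange(1, n_items + 1), n),
            "rating": items.ravel(),
        }))

    # ISI: band-constrained totals
    lows = np.array([ISI_BAND[GROUPS[g]][0] for g in group_idx])
    highs = np.array([ISI_BAND[GROUPS[g]][1] for g in group_idx])
    isi_totals = rng.integers(lows, highs + 1)
    _emit("ISI", _compose_items(isi_totals, 7, 0, 4, rng))

    for name, (base, sd) in _SCALE_BASELINES.items():
        spec = INSTRUMENTS[Instrument(name)]
        shifts = np.array(config.shifts(name))[group_idx]
        totals = np.rint(rng.normal(base + shifts, sd))
        totals = np.clip(totals, spec.total_min, spec.total_max)
        items = _compose_items(totals, spec.scored_items, spec.item_min, spec.item_max, rng)
        if spec.n_scored is not None and spec.n_scored < spec.n_items:
            extra = rng.integers(spec.item_min, spec.item_max + 1,
                                 size=(n, spec.n_items - spec.n_scored))
            items = np.hstack([items, extra])
        _emit(name, items)
    return pd.concat(frames, ignore_index=True)


def generate_sleep_nights(config: CohortConfig,
                          truths: Sequence[ParticipantTruth]) -> pd.DataFrame:
    """One record per participant-night, identically distributed across groups.

    Severity groups share the same sleep distributions by design — the
    generator encodes the null finding that subjective severity does not
    show up in device-measured sleep. Stage durations are rescaled where
    needed so REM + light + deep never exceeds the night's sleep time,
    and total inactive time is sleep time plus awake time by construction.
    """
    rng = _rng(config, 3)
    n, d = len(truths), config.study_days
    tst_p = rng.normal(config.tst_mean, config.tst_between_sd, size=n)
    awake_p = rng.normal(config.awake_mean, config.awake_between_sd, size=n)
    tst = rng.normal(tst_p[:, None], config.tst_night_sd, size=(n, d))
    awake = rng.normal(awake_p[:, None], config.awake_night_sd, size=(n, d))
    tst = np.clip(tst, 120.0, None)
    awake = np.clip(awake, 5.0, None)
    rem_m, light_m, deep_m = config.stage_means
    rem = np.clip(rng.normal(rem_m, 15.0, size=(n, d)), 0.0, None)
    light = np.clip(rng.normal(light_m, 12.0, size=(n, d)), 0.0, None)
    deep = np.clip(rng.normal(deep_m, 8.0, size=(n, d)), 0.0, None)
    staged = rem + light + deep
    over = staged > tst
    scale = np.where(over, tst / np.maximum(staged, 1e-9), 1.0)
    rem, light, deep = rem * scale, light * scale, deep * scale
    lam_p = np.clip(rng.normal(config.wakeups_per_night, 0.7, size=n), 0.5, None)
    wakeups = rng.poisson(lam_p[:, None], size=(n, d))
    dates = [config.start_date + timedelta(days=k) for k in range(d)]
    pids = [t.participant_id for t in truths]
    # round stages first, then rebuild TST/inactive from the rounded
    # values so the construction invariants hold exactly in the CSV
    rem, light, deep = np.round(rem, 2), np.round(light, 2), np.round(deep, 2)
    awake = np.round(awake, 2)
    tst = np.maximum(np.round(tst, 2), rem + light + deep)
    return pd.DataFrame({
        "participant_id": np.repeat(pids, d),
        "date": np.tile([dt.isoformat() for dt in dates], n),
        "total_inactive_min": (tst + awake).ravel(),
        "total_awake_min": awake.ravel(),
        "rem_min": rem.ravel(),
        "light_min": light.ravel(),
        "deep_min": deep.ravel(),
        "n_wakeups": wakeups.ravel(),
    })


def generate_ema_log(config: CohortConfig,
                     truths: Sequence[ParticipantTruth]) -> pd.DataFrame:
    """Daily EMA entries (caffeine, alcohol, nap, stress) with time slots.

    At most one entry per kind per slot per day. Occurrence is Bernoulli
    per day at the participant's per-kind rate (stress rate carries the
    group's effect-profile shift); caffeine and alcohol amounts are
    1 + Poisson counts; nap durations and stress intensities are drawn
    from fixed categorical distributions; slot preferences differ by
    kind (caffeine skews morning, alcohol before bedtime).
    """
    rng = _rng(config, 4)
    n, d = len(truths), config.study_days
    pids = [t.participant_id for t in truths]
    dates = [(config.start_date + timedelta(days=k)).isoformat() for k in range(d)]
    slot_probs = {
        "caffeine": (0.55, 0.35, 0.10),
        "alcohol": (0.02, 0.18, 0.80),
        "nap": (0.20, 0.65, 0.15),
        "stress": (0.30, 0.40, 0.30),
    }
    rows: dict[str, list] = {"participant_id": [], "date": [], "kind": [], "slot": [],
                             "magnitude": []}
    for kind in ("caffeine", "alcohol", "nap", "stress"):
        rates = np.array([t.ema_rates[kind] for t in truths])
        occur = rng.random((n, d)) < rates[:, None]
        k = int(occur.sum())
        if k == 0:
            continue
        pi, di = np.nonzero(occur)
        slots = rng.choice(_SLOTS, size=k, p=slot_probs[kind])
        if kind == "caffeine":
            mags = (1 + rng.poisson(0.5, size=k)).astype(object)
        elif kind == "alcohol":
            mags = (1 + rng.poisson(1.0, size=k)).astype(object)
        elif kind == "nap":
            mags = rng.choice(_NAP_CATS, size=k, p=(0.55, 0.30, 0.10, 0.05)).astype(object)
        else:
            mags = rng.choice(_STRESS_LEVELS, size=k, p=(0.55, 0.32, 0.13)).astype(object)
        rows["participant_id"].extend(pids[i] for i in pi)
        rows["date"].extend(dates[j] for j in di)
        rows["kind"].extend([kind] * k)
        rows["slot"].extend(slots.tolist())
        rows["magnitude"].extend(mags.tolist())
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "date", "kind", "slot", "magnitude"])
    # at most one entry per kind per slot per day
    df = df.drop_duplicates(subset=["participant_id", "date", "kind", "slot"], keep="first")
    return df.sort_values(["participant_id", "date", "kind"], ignore_index=True)


def generate_heart_rate(config: CohortConfig, truth: ParticipantTruth,
                        noise_sd: float | None = None) -> EpochSeries:
    """Heart-rate stream: circadian cosine + Gaussian noise, clipped to 30-220 bpm."""
    rng = _rng(config, 5, truth.index)
    epd = 1440 // config.hr_epoch_minutes
    n = config.study_days * epd
    t = np.arange(n) * (config.hr_epoch_minutes / 60.0)
    sd = config.hr_noise_sd if noise_sd is None else noise_sd
    y = truth.hr_mesor + truth.hr_amplitude * np.cos(
        2 * np.pi * (t - truth.hr_acrophase_hours) / 24.0
    )
    if sd > 0:
        y = y + rng.normal(0.0, sd, size=n)
    y = np.clip(y, 30.0, 220.0)
    missing = rng.random(n) < config.missing_fraction
    return EpochSeries(
        participant_id=truth.participant_id,
        start=datetime.combine(config.start_date, datetime.min.time()),
        epoch_minutes=config.hr_epoch_minutes,
        values=y, missing=missing,
    )


def generate_steps_cumulative(config: CohortConfig, truth: ParticipantTruth,
                              noise_sigma: float = 0.8) -> EpochSeries:
    """Cumulative step counter, resetting to 0 at midnight.

    Per-epoch increments are log-normal around a diurnal rate profile
    (day rate 8 AM-10 PM, night rate otherwise), then cumulated within
    each calendar day, so the series is nondecreasing within days and
    daytime activity dominates in expectation.
    """
    rng = _rng(config, 6, truth.index)
    epd = 1440 // config.hr_epoch_minutes
    n = config.study_days * epd
    hod = (np.arange(n) * (config.hr_epoch_minutes / 60.0)) % 24.0
    rate = np.where((hod >= 8.0) & (hod < 22.0), truth.step_day_rate, truth.step_night_rate)
    if noise_sigma > 0:
        incr = rng.lognormal(np.log(rate) - noise_sigma**2 / 2.0, noise_sigma)
        # occasional fully sedentary epochs
        incr = np.where(rng.random(n) < 0.35, 0.0, incr)
    else:
        incr = rate.astype(float)
    incr = np.round(incr)
    cumulative = incr.reshape(config.study_days, epd).cumsum(axis=1).ravel()
    missing = rng.random(n) < config.missing_fraction
    return EpochSeries(
        participant_id=truth.participant_id,
        start=datetime.combine(config.start_date, datetime.min.time()),
        epoch_minutes=config.hr_epoch_minutes,
        values=cumulative, missing=missing,
    )


def generate_cohort(config: CohortConfig,
                    streams: Sequence[str] = ALL_STREAMS) -> Cohort:
    """Generate the full synthetic study (or a subset of its streams).

    Deterministic given the config: the same (config, seed) always
    yields the identical cohort, and stream seeds are independent, so
    restricting ``streams`` does not change what the remaining streams
    contain.
    """
    unknown = set(streams) - set(ALL_STREAMS)
    if unknown:
        raise ConfigurationError(f"unknown streams: {sorted(unknown)}")
    participants, truths = _generate_participants(config)
    scale_means = {
        name: tuple(base + s for s in config.shifts(name))
        for name, (base, _sd) in _SCALE_BASELINES.items()
    }
    truth = SyntheticTruth(config=config, participants=truths,
                           scale_group_means=scale_means)
    cohort = Cohort(config=config, truth=truth, participants=participants)
    if "questionnaires" in streams:
        cohort.questionnaires = generate_questionnaires(config, truths)
    if "ema" in streams:
        cohort.ema = generate_ema_log(config, truths)
    if "sleep" in streams:
        cohort.sleep = generate_sleep_nights(config, truths)
    if "heart_rate" in streams:
        cohort.heart_rate = {t.participant_id: generate_heart_rate(config, t) for t in truths}
    if "steps" in streams:
        cohort.steps = {t.participant_id: generate_steps_cumulative(config, t)
                        for t in truths}
    return cohort
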