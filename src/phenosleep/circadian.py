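"""Circadian-rhythm features from uniformly sampled wearable streams.

Implements single-cosinor analysis of heart rate and step activity,
the nonparametric rest-activity metrics (intradaily variability IV,
interdaily stability IS, least-active 5-hour level L5, most-active
10-hour level M10), differencing of cumulative step counters, and the
calendar stratifications (weekday/weekend, day 8 AM-6 PM vs night
6 PM-8 AM) used to summarize daily extrema.

Cosinor model
-------------
For a fixed period tau (24 h) the series is fit by ordinary least
squares to

    y(t) = M + beta*cos(2*pi*t/tau) + gamma*sin(2*pi*t/tau)

which is linear in (M, beta, gamma) and therefore exact and
deterministic. The rhythm parameters are MESOR ``M`` (rhythm-adjusted
mean), amplitude ``sqrt(beta^2 + gamma^2)`` (peak minus MESOR),
acrophase ``atan2(gamma, beta) * tau / (2*pi)`` — the clock time of the
fitted peak, reported in hours past midnight in [0, 24) — and goodness
of fit, the coefficient of determination R^2 of the cosine model
against the mean-only model. Participant-level parameters come from a
sliding 2-day window advanced one day at a time, averaged
arithmetically except the acrophase, which is averaged circularly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

HOURS_PER_DAY = 24.0
DEFAULT_PERIOD_HOURS = 24.0


class FitError(ValueError):
    """Raised when a window has too little data for a cosinor fit."""


class DataError(ValueError):
    """Raised for malformed input series (e.g. a decreasing cumulative counter)."""


@dataclass
class EpochSeries:
    """Uniform-interval samples of one physiological stream.

    ``start`` is the timestamp of the first sample; ``epoch_minutes``
    must divide the day. ``missing`` marks unworn/undelivered epochs;
    missing samples are ignored by every downstream computation.
    """

    participant_id: str
    start: datetime
    epoch_minutes: int
    values: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        if 1440 % self.epoch_minutes != 0:
            raise DataError(f"epoch_minutes={self.epoch_minutes} does not divide 1440")
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool) | ~np.isfinite(self.values)
        if self.missing.shape != self.values.shape:
            raise DataError("values and missing mask differ in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def epochs_per_day(self) -> int:
        return 1440 // self.epoch_minutes

    def hours_past_midnight(self) -> np.ndarray:
        """Sample times in hours since midnight of the start date (unwrapped)."""
        start_hour = self.start.hour + self.start.minute / 60.0 + self.start.second / 3600.0
        return start_hour + np.arange(len(self.values)) * (self.epoch_minutes / 60.0)

    def timestamps(self) -> list[datetime]:
        step = timedelta(minutes=self.epoch_minutes)
        return [self.start + i * step for i in range(len(self.values))]


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_hours: float  # hours past midnight of the fitted peak, in [0, 24)
    goodness_of_fit: float  # R^2 vs the mean-only model, in [0, 1]
    window_start: datetime | None = None
    n_samples: int = 0

    @property
    def acrophase_signed(self) -> float:
        """Acrophase as a signed offset from midnight in (-12, 12]."""
        a = self.acrophase_hours % HOURS_PER_DAY
        return a if a <= 12.0 else a - HOURS_PER_DAY


@dataclass(frozen=True)
class SlidingCosinorResult:
    fits: tuple[CosinorFit, ...]
    mean: CosinorFit
    n_windows_skipped: int = 0


@dataclass(frozen=True)
class L5M10:
    l5: float
    m10: float
    l5_onset_hour: float  # hours past midnight of start day, unwrapped
    m10_onset_hour: float


def difference_cumulative(series: EpochSeries, tolerance: float = 0.0) -> EpochSeries:
    """Convert a within-day cumulative counter into per-epoch increments.

    The counter resets to 0 at midnight, so the first epoch of each day
    contributes its own value as the increment from 0. A within-day
    decrease larger than ``tolerance`` raises :class:`DataError` naming
    the offending epoch.
    """
    values = series.values
    n = len(values)
    epd = series.epochs_per_day
    if series.start.hour or series.start.minute or series.start.second:
        raise DataError("cumulative differencing requires a midnight-aligned series")
    prev = np.empty(n)
    prev[0] = 0.0
    prev[1:] = values[:-1]
    day_first = np.arange(n) % epd == 0
    prev[day_first] = 0.0
    increments = values - prev
    bad = np.where(~day_first & (increments < -tolerance))[0]
    bad = [int(i) for i in bad if not (series.missing[i] or series.missing[i - 1])]
    if bad:
        raise DataError(f"cumulative counter decreases within a day at epoch {bad[0]}")
    increments = np.clip(increments, 0.0, None)
    return EpochSeries(
        participant_id=series.participant_id,
        start=series.start,
        epoch_minutes=series.epoch_minutes,
        values=increments,
        missing=series.missing.copy(),
    )


def cosinor_fit(
    series: EpochSeries,
    period_hours: float = DEFAULT_PERIOD_HOURS,
    _t: np.ndarray | None = None,
    _window_start: datetime | None = None,
) -> CosinorFit:
    """Least-squares single-cosinor fit at a fixed period.

    Requires at least 3 non-missing samples. A zero-variance series
    returns amplitude 0 and goodness of fit 0 by convention.
    """
    t = series.hours_past_midnight() if _t is None else _t
    keep = ~series.missing
    y = series.values[keep]
    t = t[keep]
    if len(y) < 3:
        raise FitError(f"cosinor fit needs >= 3 non-missing samples, got {len(y)}")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return CosinorFit(
            mesor=float(y[0]), amplitude=0.0, acrophase_hours=0.0,
            goodness_of_fit=0.0, window_start=_window_start or series.start,
            n_samples=len(y),
        )
    omega = 2.0 * math.pi / period_hours
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    amplitude = math.hypot(beta, gamma)
    acrophase = (math.atan2(gamma, beta) / omega) % HOURS_PER_DAY
    residual = y - X @ coef
    r2 = 1.0 - float(np.sum(residual**2)) / sst
    r2 = min(max(r2, 0.0), 1.0)
    return CosinorFit(
        mesor=mesor, amplitude=amplitude, acrophase_hours=acrophase,
        goodness_of_fit=r2, window_start=_window_start or series.start,
        n_samples=len(y),
    )


def circular_mean_hours(hours: Sequence[float], period: float = HOURS_PER_DAY) -> float:
    """Vector mean of clock times on a ``period``-hour circle, in [0, period)."""
    angles = 2.0 * math.pi * np.asarray(hours, dtype=float) / period
    s, c = float(np.mean(np.sin(angles))), float(np.mean(np.cos(angles)))
    return (math.atan2(s, c) * period / (2.0 * math.pi)) % period


def sliding_cosinor(
    series: EpochSeries,
    window_days: int = 2,
    step_days: int = 1,
    period_hours: float = DEFAULT_PERIOD_HOURS,
    min_coverage: float = 0.5,
) -> SlidingCosinorResult:
    """Cosinor parameters from a sliding multi-day window.

    One fit per window position (default: 2-day windows advanced by one
    day). Windows with less than ``min_coverage`` non-missing samples
    are skipped and counted. Participant-level parameters are the
    arithmetic means of MESOR, amplitude and goodness of fit across
    windows, and the circular mean of the acrophase.
    """
    epd = series.epochs_per_day
    n_days = len(series) // epd
    if n_days < window_days:
        raise FitError(f"series spans {n_days} full days; window needs {window_days}")
    t_all = series.hours_past_midnight()
    fits: list[CosinorFit] = []
    skipped = 0
    wlen = window_days * epd
    for start_day in range(0, n_days - window_days + 1, step_days):
        lo = start_day * epd
        sl = slice(lo, lo + wlen)
        sub_missing = series.missing[sl]
        if (~sub_missing).sum() < min_coverage * wlen:
            skipped += 1
            continue
        sub = EpochSeries(
            participant_id=series.participant_id,
            start=series.start + timedelta(days=start_day),
            epoch_minutes=series.epoch_minutes,
            values=series.values[sl],
            missing=sub_missing,
        )
        try:
            fits.append(cosinor_fit(sub, period_hours, _t=t_all[sl], _window_start=sub.start))
        except FitError:
            skipped += 1
    if not fits:
        raise FitError("no window had enough data for a cosinor fit")
    mean_fit = CosinorFit(
        mesor=float(np.mean([f.mesor for f in fits])),
        amplitude=float(np.mean([f.amplitude for f in fits])),
        acrophase_hours=circular_mean_hours([f.acrophase_hours for f in fits], period_hours),
        goodness_of_fit=float(np.mean([f.goodness_of_fit for f in fits])),
        window_start=series.start,
        n_samples=int(sum(f.n_samples for f in fits)),
    )
    return SlidingCosinorResult(fits=tuple(fits), mean=mean_fit, n_windows_skipped=skipped)


def _binned_means(series: EpochSeries, bin_minutes: int, min_coverage: float = 0.5):
    """Means of consecutive ``bin_minutes`` bins; bins under coverage → NaN."""
    if bin_minutes % series.epoch_minutes != 0:
        raise DataError("bin_minutes must be a multiple of epoch_minutes")
    if 1440 % bin_minutes != 0:
        raise DataError("bin_minutes must divide the day")
    k = bin_minutes // series.epoch_minutes
    n_bins = len(series) // k
    vals = series.values[: n_bins * k].reshape(n_bins, k)
    present = (~series.missing[: n_bins * k]).reshape(n_bins, k)
    counts = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(present, vals, 0.0).sum(axis=1) / counts
    means[counts < min_coverage * k] = np.nan
    return means


def intradaily_variability(series: EpochSeries, bin_minutes: int = 60) -> float:
    """Fragmentation of the rhythm: normalized mean squared successive difference.

    On the hourly-binned series x_1..x_n:

        IV = n * sum_i (x_i - x_{i-1})^2 / [(n - 1) * sum_i (x_i - xbar)^2]

    ~0 for a smooth sinusoid, ~2 for white noise, >2 for ultradian
    alternation. Successive differences across a dropped (low-coverage)
    bin are excluded. Returns NaN when variance is zero.
    """
    x = _binned_means(series, bin_minutes)
    valid = np.isfinite(x)
    xs = x[valid]
    n = len(xs)
    if n < 2:
        raise DataError("IV needs >= 2 valid bins")
    denom_var = float(np.sum((xs - xs.mean()) ** 2))
    if denom_var == 0.0:
        return float("nan")
    pair = valid[1:] & valid[:-1]
    diffs = (x[1:] - x[:-1])[pair]
    return float(n * np.sum(diffs**2) / ((n - 1) * denom_var))


def interdaily_stability(series: EpochSeries, bin_minutes: int = 60) -> float:
    """Day-to-day constancy of the 24-h profile, in [0, 1].

    With p bins per day and hourly means xbar_h pooled across days:

        IS = n * sum_h (xbar_h - xbar)^2 / [p * sum_i (x_i - xbar)^2]

    1 means a perfectly repeating daily pattern; white noise over many
    days approaches 0. Returns NaN when variance is zero.
    """
    if len(series) < 2 * series.epochs_per_day:
        raise DataError("IS needs >= 2 full days")
    x = _binned_means(series, bin_minutes)
    p = 1440 // bin_minutes
    n_days = len(x) // p
    x = x[: n_days * p]
    valid = np.isfinite(x)
    xs = x[valid]
    n = len(xs)
    if n < 2:
        raise DataError("IS needs >= 2 valid bins")
    grand = xs.mean()
    denom = float(np.sum((xs - grand) ** 2))
    if denom == 0.0:
        return float("nan")
    prof = np.nanmean(x.reshape(n_days, p), axis=0)
    hourly_valid = np.isfinite(prof)
    num = float(n * np.sum((prof[hourly_valid] - grand) ** 2))
    return num / (p * denom)


def l5_m10(series: EpochSeries, min_coverage: float = 0.5) -> L5M10:
    """Least-active 5-h and most-active 10-h levels by moving average.

    L5 is the minimum of the 5-hour moving average over all complete
    window positions; M10 the maximum of the 10-hour moving average.
    Windows with under ``min_coverage`` non-missing samples are
    ignored. Onset times are in hours from midnight of the start day.
    """
    hours_span = len(series) * series.epoch_minutes / 60.0
    if hours_span < 10.0:
        raise DataError("L5/M10 need a series spanning >= 10 h")

    def _windowed(width_hours: float):
        w = int(round(width_hours * 60.0 / series.epoch_minutes))
        vals = np.where(series.missing, 0.0, series.values)
        cnts = (~series.missing).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        ccnt = np.concatenate([[0.0], np.cumsum(cnts)])
        sums = csum[w:] - csum[:-w]
        counts = ccnt[w:] - ccnt[:-w]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts
        means[counts < min_coverage * w] = np.nan
        return means

    ma5 = _windowed(5.0)
    ma10 = _windowed(10.0)
    if not np.isfinite(ma5).any() or not np.isfinite(ma10).any():
        raise DataError("insufficient non-missing coverage for L5/M10")
    t = series.hours_past_midnight()
    i5 = int(np.nanargmin(ma5))
    i10 = int(np.nanargmax(ma10))
    return L5M10(
        l5=float(ma5[i5]), m10=float(ma10[i10]),
        l5_onset_hour=float(t[i5]), m10_onset_hour=float(t[i10]),
    )


def stratified_aggregates(
    series: EpochSeries,
    day_start_hour: float = 8.0,
    day_end_hour: float = 18.0,
) -> dict[str, dict[str, float]]:
    """Daily max/min/mean averaged by weekday/weekend and by day/night.

    The "day" segment runs ``day_start_hour``-``day_end_hour`` (8 AM to
    6 PM by default); "night" is the complement, 6 PM through 8 AM, with
    the post-midnight stretch attributed to the evening's date. Weekday/
    weekend membership comes from the calendar date of the series start.
    Returns ``{stratum: {"max": ..., "min": ..., "mean": ...}}`` for the
    strata all / weekday / weekend / day / night; strata with no data
    are omitted.
    """
    import pandas as pd

    ts = pd.DatetimeIndex(series.timestamps())
    df = pd.DataFrame({"value": series.values, "missing": series.missing}, index=ts)
    df = df[~df["missing"]]
    if df.empty:
        return {}
    hod = df.index.hour + df.index.minute / 60.0
    in_day = (hod >= day_start_hour) & (hod < day_end_hour)
    # attribute the after-midnight part of the night to the previous evening
    night_date = df.index.normalize().where(hod >= day_end_hour, df.index.normalize() - pd.Timedelta(days=1))
    seg_date = df.index.normalize().where(in_day, night_date)
    df = df.assign(in_day=in_day, seg_date=seg_date, date=df.index.normalize())

    def _daily_stats(sub: "pd.DataFrame", by: str) -> dict[str, float] | None:
        if sub.empty:
            return None
        daily = sub.groupby(by)["value"].agg(["max", "min", "mean"])
        return {k: float(daily[k].mean()) for k in ("max", "min", "mean")}

    out: dict[str, dict[str, float]] = {}
    strata = {
        "all": (df, "date"),
        "weekday": (df[df["date"].dt.dayofweek < 5], "date"),
        "weekend": (df[df["date"].dt.dayofweek >= 5], "date"),
        "day": (df[df["in_day"]], "seg_date"),
        "night": (df[~df["in_day"]], "seg_date"),
    }
    for name, (sub, by) in strata.items():
        stats = _daily_stats(sub, by)
        if stats is not None:
            out[name] = stats
    return out
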