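"""Feature extraction and the end-to-end four-group analysis.

Binds the stage modules together on tabular inputs: questionnaire
scoring → scored_scales, EMA weighting → per-participant behavior
variables, nightly records → sleep summaries, wearable streams →
cosinor and nonparametric circadian features, and finally the
ISI-banded four-group comparison over every derived variable.
"""

from __future__ import annotations

from datetime import date as Date
from typing import Mapping, Sequence

import pandas as pd

from . import analysis, circadian, ema, questionnaires, sleep
from .circadian import EpochSeries


def score_questionnaires(items: pd.DataFrame) -> pd.DataFrame:
    """Score item-level responses into one row per participant-instrument.

    Expects columns participant_id, instrument, item_index, rating and
    optionally sex (needed for the AUDIT-C risk category).
    """
    _require(items, ["participant_id", "instrument", "item_index", "rating"], "questionnaires")
    rows = []
    for (pid, inst), sub in items.groupby(["participant_id", "instrument"], sort=True):
        sub = sub.sort_values("item_index")
        sex = sub["sex"].iloc[0] if "sex" in sub.columns else None
        resp = questionnaires.QuestionnaireResponse(
            instrument=questionnaires.Instrument(inst),
            items=tuple(int(r) for r in sub["rating"]),
            respondent_sex=sex,
        )
        scored = questionnaires.score(resp)
        rows.append({"participant_id": pid, "instrument": inst,
                     "total": scored.total, "category": scored.category})
    return pd.DataFrame(rows)


def ema_features(entries: pd.DataFrame, study_days: int = 28,
                 statistic: str = "sum") -> pd.DataFrame:
    """Per-participant time-weighted caffeine/alcohol/nap/stress variables.

    Vectorized equivalent of :func:`phenosleep.ema.aggregate_participant`
    applied to every participant in the table: encode, weight by
    (kind, slot), sum over the study period (or divide by ``study_days``
    for the mean-per-day statistic). Participants never reporting a kind
    get 0 for it.
    """
    _require(entries, ["participant_id", "date", "kind", "slot", "magnitude"], "ema")
    if statistic not in ("sum", "mean_per_day"):
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    df = entries.copy()
    if df.empty:
        return pd.DataFrame(columns=["participant_id", *ema.KINDS])
    bad_kind = ~df["kind"].isin(ema.KINDS)
    if bad_kind.any():
        raise ema.EMAError(f"unknown EMA kind {df.loc[bad_kind, 'kind'].iloc[0]!r}")
    bad_slot = ~df["slot"].isin(ema.SLOTS)
    if bad_slot.any():
        raise ema.EMAError(f"unknown time-of-day slot {df.loc[bad_slot, 'slot'].iloc[0]!r}")
    enc = pd.to_numeric(df["magnitude"], errors="coerce")
    nap_mask = df["kind"] == "nap"
    stress_mask = df["kind"] == "stress"
    enc[nap_mask] = df.loc[nap_mask, "magnitude"].map(ema.encode_nap)
    enc[stress_mask] = df.loc[stress_mask, "magnitude"].map(ema.encode_stress)
    if enc.isna().any():
        bad = df.loc[enc.isna()].iloc[0]
        raise ema.EMAError(f"unencodable magnitude {bad['magnitude']!r} for kind {bad['kind']}")
    weight = pd.Series(
        [ema.DEFAULT_WEIGHTS[k][ema.SLOTS.index(s)] for k, s in zip(df["kind"], df["slot"])],
        index=df.index,
    )
    df["weighted"] = enc * weight
    agg = (df.groupby(["participant_id", "kind"])["weighted"].sum()
             .unstack(fill_value=0.0)
             .reindex(columns=list(ema.KINDS), fill_value=0.0))
    if statistic == "mean_per_day":
        agg = agg / study_days
    # every participant appearing in the table gets a row, even if all kinds absent
    agg = agg.reindex(sorted(entries["participant_id"].unique()), fill_value=0.0)
    return agg.rename_axis("participant_id").reset_index()


def sleep_features(nights: pd.DataFrame, quality_mode: str = "aggregated") -> pd.DataFrame:
    """Per-participant 4-week sleep summaries (Table-1-style columns)."""
    _require(nights, ["participant_id", "date", "total_inactive_min", "total_awake_min",
                      "rem_min", "light_min", "deep_min", "n_wakeups"], "sleep")
    rows = []
    for pid, sub in nights.groupby("participant_id", sort=True):
        records = [
            sleep.SleepNight(
                participant_id=str(pid), date=_as_date(r.date),
                total_inactive_min=float(r.total_inactive_min),
                total_awake_min=float(r.total_awake_min),
                rem_min=float(r.rem_min), light_min=float(r.light_min),
                deep_min=float(r.deep_min), n_wakeups=int(r.n_wakeups),
            )
            for r in sub.itertuples()
        ]
        s = sleep.summarize_participant(records, quality_mode=quality_mode)
        rows.append({
            "participant_id": pid, "tst_min": s.tst_min, "awake_min": s.awake_min,
            "rem_min": s.rem_min, "light_min": s.light_min, "deep_min": s.deep_min,
            "wakeups_per_week": s.wakeups_per_week,
            "sleep_quality_pct": s.sleep_quality_pct, "n_nights": s.n_nights,
        })
    return pd.DataFrame(rows)


def circadian_features(
    heart_rate: Mapping[str, EpochSeries] | None = None,
    steps: Mapping[str, EpochSeries] | None = None,
    window_days: int = 2,
    iv_is_stream: str = "steps",
) -> pd.DataFrame:
    """Per-participant circadian feature block (Table-2-style columns).

    Sliding 2-day cosinor parameters for heart rate and for differenced
    step increments; IV/IS/L5/M10 on the step increments by default
    (``iv_is_stream="heart_rate"`` switches them to heart rate); plus
    stratified day/night and weekday/weekend mean levels of each stream.
    """
    pids = sorted(set(heart_rate or {}) | set(steps or {}))
    rows = []
    for pid in pids:
        row: dict[str, float | str] = {"participant_id": pid}
        hr = heart_rate.get(pid) if heart_rate else None
        st = steps.get(pid) if steps else None
        increments = circadian.difference_cumulative(st) if st is not None else None
        if hr is not None:
            fit = circadian.sliding_cosinor(hr, window_days=window_days).mean
            row.update(hr_mesor=fit.mesor, hr_amplitude=fit.amplitude,
                       hr_acrophase=fit.acrophase_hours,
                       hr_goodness_of_fit=fit.goodness_of_fit)
            strat = circadian.stratified_aggregates(hr)
            for stratum, stats_ in strat.items():
                row[f"hr_{stratum}_mean"] = stats_["mean"]
        if increments is not None:
            fit = circadian.sliding_cosinor(increments, window_days=window_days).mean
            row.update(steps_mesor=fit.mesor, steps_amplitude=fit.amplitude,
                       steps_acrophase=fit.acrophase_hours,
                       steps_goodness_of_fit=fit.goodness_of_fit)
            strat = circadian.stratified_aggregates(increments)
            for stratum, stats_ in strat.items():
                row[f"steps_{stratum}_mean"] = stats_["mean"]
        rhythm_series = hr if iv_is_stream == "heart_rate" else increments
        if rhythm_series is not None:
            row["iv"] = circadian.intradaily_variability(rhythm_series)
            row["is"] = circadian.interdaily_stability(rhythm_series)
            lm = circadian.l5_m10(rhythm_series)
            row["l5"] = lm.l5
            row["m10"] = lm.m10
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_CATEGORICAL = ("IRLS", "PHQ9", "GAD7", "AUDIT_C", "SOS_Q")


def run_group_analysis(
    scored_scales: pd.DataFrame,
    features: Sequence[pd.DataFrame] = (),
    participants: pd.DataFrame | None = None,
    group_on: str = "ISI",
    policy: analysis.StatisticalPolicy = analysis.StatisticalPolicy(),
) -> dict:
    """ISI-band the cohort and compare every variable across the 4 groups.

    ``group_on="ISI"`` bands the scored follow-up ISI totals;
    ``group_on="isi_screening"`` instead bands the screening totals from
    the participants table. Continuous variables are all scale totals
    plus every numeric feature column; instrument categories are added
    as categorical variables. Returns ``{"groups": counts, "results":
    [ComparisonResult...], "report": rows}``.
    """
    if group_on == "ISI":
        isi = scored_scales[scored_scales["instrument"] == "ISI"]
        key = isi.set_index("participant_id")["total"]
    elif group_on == "isi_screening":
        if participants is None:
            raise ValueError("isi_screening grouping needs the participants table")
        key = participants.set_index("participant_id")["isi_screening_total"]
    else:
        raise ValueError(f"unknown grouping source {group_on!r}")
    labels, counts = analysis.assign_groups(key.to_list())
    group_of = dict(zip(key.index, labels))

    results: list[analysis.ComparisonResult] = []
    # continuous scale totals (skip the grouping scale itself)
    for inst, sub in scored_scales.groupby("instrument"):
        if inst == "ISI":
            continue
        g = [group_of[p] for p in sub["participant_id"]]
        results.append(analysis.test_variable(f"{inst}_total", sub["total"].to_numpy(),
                                              g, "continuous", policy))
        if inst in DEFAULT_CATEGORICAL and sub["category"].notna().any():
            results.append(analysis.test_variable(f"{inst}_index", sub["category"].to_list(),
                                                  g, "categorical", policy))
    for feat in features:
        if feat is None or feat.empty:
            continue
        g = [group_of.get(p) for p in feat["participant_id"]]
        keep = [i for i, gg in enumerate(g) if gg is not None]
        for col in feat.columns:
            if col in ("participant_id", "n_nights") or not pd.api.types.is_numeric_dtype(feat[col]):
                continue
            vals = feat[col].to_numpy()[keep]
            results.append(analysis.test_variable(col, vals, [g[i] for i in keep],
                                                  "continuous", policy))
    return {
        "groups": counts,
        "results": results,
        "report": analysis.build_report(results),
    }


def _as_date(value) -> Date:
    if isinstance(value, Date):
        return value
    return pd.Timestamp(value).date()


def _require(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing column(s): {', '.join(missing)}")
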