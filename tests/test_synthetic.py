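"""Synthetic cohort generator: determinism, banding, nulls, and recovery."""

import numpy as np
import pandas as pd
import pytest

from phenosleep import (
    CohortConfig,
    cosinor_fit,
    difference_cumulative,
    generate_cohort,
    generate_heart_rate,
    generate_steps_cumulative,
)
from phenosleep import synthetic
from phenosleep.questionnaires import INSTRUMENTS, Instrument
from phenosleep.synthetic import ISI_BAND, ConfigurationError, apportion_counts


class TestConfig:
    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(group_proportions=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ConfigurationError):
            CohortConfig(group_proportions=(0.3, 0.3, 0.3, 0.2))

    def test_too_short_study_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(study_days=1)

    def test_epoch_must_divide_day(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(hr_epoch_minutes=7)


class TestGroupStructure:
    def test_default_proportions_reproduce_study_counts(self):
        counts = apportion_counts((0.252, 0.424, 0.276, 0.048), 250)
        assert counts == [63, 106, 69, 12]

    def test_cohort_group_counts_at_full_size(self):
        cohort = generate_cohort(CohortConfig(n_participants=250, seed=5),
                                 streams=("questionnaires",))
        vc = cohort.participants["group_true"].value_counts()
        assert vc["no_insomnia"] == 63 and vc["mild"] == 106
        assert vc["moderate"] == 69 and vc["severe"] == 12

    def test_single_group_degenerate_case(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=4, group_proportions=(1, 0, 0, 0), seed=0),
            streams=("questionnaires",))
        isi = cohort.questionnaires.query("instrument == 'ISI'")
        totals = isi.groupby("participant_id")["rating"].sum()
        assert (totals <= 7).all()

    def test_isi_totals_always_inside_group_band(self, small_cohort):
        isi = small_cohort.questionnaires.query("instrument == 'ISI'")
        totals = isi.groupby("participant_id")["rating"].sum()
        groups = small_cohort.participants.set_index("participant_id")["group_true"]
        for pid, total in totals.items():
            lo, hi = ISI_BAND[groups[pid]]
            assert lo <= total <= hi


class TestDeterminism:
    def test_identical_config_and_seed_identical_cohort(self):
        cfg = CohortConfig(n_participants=8, seed=42, study_days=3)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.questionnaires, b.questionnaires)
        pd.testing.assert_frame_equal(a.ema, b.ema)
        pd.testing.assert_frame_equal(a.sleep, b.sleep)
        for pid in a.heart_rate:
            np.testing.assert_array_equal(a.heart_rate[pid].values, b.heart_rate[pid].values)
            np.testing.assert_array_equal(a.steps[pid].values, b.steps[pid].values)

    def test_stream_subset_does_not_change_other_streams(self):
        cfg = CohortConfig(n_participants=6, seed=9, study_days=3)
        full = generate_cohort(cfg)
        only_sleep = generate_cohort(cfg, streams=("sleep",))
        pd.testing.assert_frame_equal(full.sleep, only_sleep.sleep)


class TestQuestionnaireGeneration:
    def test_all_item_ratings_in_legal_ranges(self, small_cohort):
        for inst, sub in small_cohort.questionnaires.groupby("instrument"):
            spec = INSTRUMENTS[Instrument(inst)]
            assert sub["rating"].between(spec.item_min, spec.item_max).all()
            per_pid = sub.groupby("participant_id").size()
            assert (per_pid == spec.n_items).all()

    def test_zero_effect_profile_removes_group_differences(self):
        profile = {k: (0.0, 0.0, 0.0, 0.0) for k in synthetic.DEFAULT_EFFECT_PROFILE}
        cfg = CohortConfig(n_participants=400, seed=13, effect_profile=profile)
        cohort = generate_cohort(cfg, streams=("questionnaires",))
        dbas = cohort.questionnaires.query("instrument == 'DBAS'")
        totals = dbas.groupby("participant_id")["rating"].sum()
        groups = cohort.participants.set_index("participant_id")["group_true"]
        means = totals.groupby(groups).mean()
        spread = means.loc[["no_insomnia", "mild", "moderate"]]
        assert spread.max() - spread.min() < 8  # no systematic gradient

    def test_dbas_group_means_recovered_within_two_se(self):
        cfg = CohortConfig(n_participants=250, seed=21)
        cohort = generate_cohort(cfg, streams=("questionnaires",))
        dbas = cohort.questionnaires.query("instrument == 'DBAS'")
        totals = dbas.groupby("participant_id")["rating"].sum()
        groups = cohort.participants.set_index("participant_id")["group_true"]
        target = dict(zip(synthetic.GROUPS,
                          cohort.truth.scale_group_means["DBAS"]))
        sd = 23.56
        for g, sample in totals.groupby(groups):
            se = sd / np.sqrt(len(sample))
            assert abs(sample.mean() - target[g]) < 2.5 * se


class TestSleepGeneration:
    def test_construction_invariants_every_night(self, small_cohort):
        df = small_cohort.sleep
        tst = df["total_inactive_min"] - df["total_awake_min"]
        staged = df["rem_min"] + df["light_min"] + df["deep_min"]
        assert (staged <= tst + 1e-9).all()
        assert (df["total_awake_min"] <= df["total_inactive_min"]).all()
        assert (df[["rem_min", "light_min", "deep_min"]] >= 0).all().all()

    def test_one_record_per_participant_night(self, small_cohort):
        counts = small_cohort.sleep.groupby("participant_id").size()
        assert (counts == small_cohort.config.study_days).all()

    def test_groups_share_sleep_distribution(self):
        # pooled over seeds, group medians of mean TST stay close
        cfg = CohortConfig(n_participants=300, seed=3)
        cohort = generate_cohort(cfg, streams=("sleep",))
        mean_tst = (cohort.sleep.assign(
            tst=cohort.sleep.total_inactive_min - cohort.sleep.total_awake_min)
            .groupby("participant_id")["tst"].mean())
        groups = cohort.participants.set_index("participant_id")["group_true"]
        medians = mean_tst.groupby(groups).median().drop("severe")  # tiny group noisy
        assert medians.max() - medians.min() < 15


class TestWearableStreams:
    def test_flat_rhythm_with_no_noise_is_constant(self):
        cfg = CohortConfig(n_participants=1, seed=1, study_days=2,
                           missing_fraction=0.0, hr_noise_sd=0.0)
        truth = generate_cohort(cfg, streams=()).truth.participants[0]
        flat = synthetic.ParticipantTruth(**{**truth.__dict__, "hr_amplitude": 0.0})
        series = generate_heart_rate(cfg, flat, noise_sd=0.0)
        np.testing.assert_allclose(series.values, flat.hr_mesor)

    def test_cosine_extremes_at_acrophase_and_antiphase(self):
        cfg = CohortConfig(n_participants=1, seed=1, study_days=2,
                           missing_fraction=0.0, hr_noise_sd=0.0)
        base = generate_cohort(cfg, streams=()).truth.participants[0]
        truth = synthetic.ParticipantTruth(**{
            **base.__dict__, "hr_mesor": 75.0, "hr_amplitude": 10.0,
            "hr_acrophase_hours": 15.0})
        series = generate_heart_rate(cfg, truth, noise_sd=0.0)
        t = series.hours_past_midnight()
        assert series.values[np.argmin(np.abs(t - 15.0))] == pytest.approx(85.0)
        assert series.values[np.argmin(np.abs(t - 3.0))] == pytest.approx(65.0)

    def test_default_hr_parameters_near_study_scale(self):
        cfg = CohortConfig(n_participants=60, seed=17, study_days=4)
        cohort = generate_cohort(cfg, streams=("heart_rate",))
        fits = [cosinor_fit(s) for s in cohort.heart_rate.values()]
        assert 70 < np.median([f.mesor for f in fits]) < 80
        assert 8 < np.median([f.amplitude for f in fits]) < 14

    def test_cumulative_steps_nondecreasing_within_days(self, small_cohort):
        for series in small_cohort.steps.values():
            epd = series.epochs_per_day
            per_day = series.values.reshape(-1, epd)
            assert (np.diff(per_day, axis=1) >= 0).all()

    def test_increments_telescope_to_daily_totals(self, small_cohort):
        series = next(iter(small_cohort.steps.values()))
        inc = difference_cumulative(series)
        epd = series.epochs_per_day
        daily_sums = inc.values.reshape(-1, epd).sum(axis=1)
        daily_finals = series.values.reshape(-1, epd)[:, -1]
        np.testing.assert_allclose(daily_sums, daily_finals)

    def test_daytime_activity_exceeds_night(self):
        cfg = CohortConfig(n_participants=1, seed=2, study_days=4, missing_fraction=0.0)
        truth = generate_cohort(cfg, streams=()).truth.participants[0]
        inc = difference_cumulative(generate_steps_cumulative(cfg, truth)).values
        hod = np.arange(len(inc)) * cfg.hr_epoch_minutes / 60.0 % 24
        day = inc[(hod >= 8) & (hod < 22)].mean()
        night = inc[(hod < 8) | (hod >= 22)].mean()
        assert day > night

    def test_noiseless_steps_form_daily_ramps(self):
        cfg = CohortConfig(n_participants=1, seed=2, study_days=2, missing_fraction=0.0)
        truth = generate_cohort(cfg, streams=()).truth.participants[0]
        series = generate_steps_cumulative(cfg, truth, noise_sigma=0.0)
        inc = difference_cumulative(series).values
        hod = np.arange(len(inc)) * cfg.hr_epoch_minutes / 60.0 % 24
        assert np.allclose(np.unique(inc[(hod >= 8) & (hod < 22)]),
                           round(truth.step_day_rate))


class TestEMAGeneration:
    def test_entries_use_legal_enumerations(self, small_cohort):
        df = small_cohort.ema
        assert df["kind"].isin(["caffeine", "alcohol", "nap", "stress"]).all()
        assert df["slot"].isin(["morning", "afternoon", "before_bedtime"]).all()
        naps = df.query("kind == 'nap'")["magnitude"]
        assert naps.isin(["<1h", "1-2h", "2-3h", ">3h"]).all()
        stress = df.query("kind == 'stress'")["magnitude"]
        assert stress.isin(["mild", "moderate", "severe"]).all()

    def test_at_most_one_entry_per_kind_slot_day(self, small_cohort):
        dup = small_cohort.ema.duplicated(["participant_id", "date", "kind", "slot"])
        assert not dup.any()

    def test_stress_rates_graded_by_group(self):
        cfg = CohortConfig(n_participants=300, seed=23)
        cohort = generate_cohort(cfg, streams=("ema",))
        counts = (cohort.ema.query("kind == 'stress'")
                  .groupby("participant_id").size())
        groups = cohort.participants.set_index("participant_id")["group_true"]
        counts = counts.reindex(groups.index, fill_value=0)
        medians = counts.groupby(groups).median()
        assert medians["no_insomnia"] < medians["mild"]
        assert medians["no_insomnia"] < medians["severe"]


class TestTruthSeparation:
    def test_analysis_modules_never_import_the_generator(self):
        import phenosleep.analysis, phenosleep.circadian, phenosleep.ema
        import phenosleep.pipeline, phenosleep.questionnaires, phenosleep.sleep
        for mod in (phenosleep.analysis, phenosleep.circadian, phenosleep.ema,
                    phenosleep.pipeline, phenosleep.questionnaires, phenosleep.sleep):
            source = open(mod.__file__).read()
            assert "synthetic" not in source
            assert "SyntheticTruth" not in source
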