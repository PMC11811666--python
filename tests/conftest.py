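from datetime import datetime

import numpy as np
import pytest

from phenosleep import CohortConfig, EpochSeries, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small full cohort (all streams) shared across tests."""
    config = CohortConfig(n_participants=16, seed=11, study_days=7)
    return generate_cohort(config)


def make_series(values, epoch_minutes=5, start=datetime(2023, 3, 6), missing=None,
                pid="p1") -> EpochSeries:
    return EpochSeries(participant_id=pid, start=start, epoch_minutes=epoch_minutes,
                       values=np.asarray(values, dtype=float), missing=missing)


def cosine_series(mesor, amplitude, acrophase_hours, days=2, epoch_minutes=5,
                  noise_sd=0.0, seed=0, start=datetime(2023, 3, 6)) -> EpochSeries:
    n = days * 1440 // epoch_minutes
    t = np.arange(n) * epoch_minutes / 60.0
    y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_hours) / 24.0)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, n)
    return make_series(y, epoch_minutes=epoch_minutes, start=start)
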