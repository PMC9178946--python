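import numpy as np
import pytest

from rrespstate.preprocess import EvenSeries
from rrespstate.synth import StateSchedule, generate_cohort, generate_register
from rrespstate.windows import AnalysisWindow


@pytest.fixture(scope="session")
def small_cohort_table():
    """Labeled feature table of 5 synthetic subjects, 150 s per state."""
    return generate_cohort(
        n_subjects=5, schedule=StateSchedule.three_stage(150.0), seed=7
    )


@pytest.fixture(scope="session")
def default_register():
    """One default-protocol synthetic register (300 s per state, seed 7)."""
    return generate_register(StateSchedule.three_stage(), seed=7)


def make_window(
    rr_values,
    eda_values,
    window_s=20.0,
    rr_beats=None,
    label=None,
    eda_dt=None,
):
    """Hand-built analysis window on [0, window_s) for feature unit tests."""
    rr_values = np.asarray(rr_values, dtype=float)
    eda_values = np.asarray(eda_values, dtype=float)
    rr_dt = window_s / rr_values.size
    eda_dt = eda_dt or window_s / eda_values.size
    if rr_beats is None:
        rr_beats = np.full(20, float(np.mean(rr_values)))
    beat_times = np.cumsum(rr_beats)
    return AnalysisWindow(
        index=0,
        t_start=0.0,
        t_end=window_s,
        rr_grid=EvenSeries(0.0, rr_dt, rr_values),
        rr_beats=np.asarray(rr_beats, dtype=float),
        beat_times=beat_times,
        eda_grid=EvenSeries(0.0, eda_dt, eda_values),
        label=label,
    )
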