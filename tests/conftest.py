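import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from pulsedetect.design import SessionPlan
from pulsedetect.observer import PopulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_plan():
    return SessionPlan()


@pytest.fixture(scope="session")
def small_cohort():
    """Four participants, full-size sessions; used by structural tests."""
    return simulate_cohort(4, seed=11)


@pytest.fixture(scope="session")
def full_cohort_null():
    """36 participants, no entrainment (the study-sized null cohort)."""
    return simulate_cohort(36, seed=5, entrain_amp=0.0)


def make_trials(bins, hits, extra_catch=0, n_no_response=0,
                participant="p00", condition="sham", order="sham_first"):
    """Hand-built minimal trial table for binning tests."""
    rows = []
    i = 0
    for b, h in zip(bins, hits):
        rows.append(dict(
            participant_id=participant, condition=condition, order=order,
            block=0, trial=i, tsoa=200.0, catch=False,
            pulse_soa=b * 10.0 + 5.0, luminance=0.5,
            response="hit" if h else "miss", rt=300.0 if h else np.nan,
        ))
        i += 1
    for _ in range(extra_catch):
        rows.append(dict(
            participant_id=participant, condition=condition, order=order,
            block=0, trial=i, tsoa=200.0, catch=True,
            pulse_soa=15.0, luminance=0.5,
            response="correct_rejection", rt=np.nan,
        ))
        i += 1
    for _ in range(n_no_response):
        rows.append(dict(
            participant_id=participant, condition=condition, order=order,
            block=0, trial=i, tsoa=200.0, catch=False,
            pulse_soa=25.0, luminance=0.5,
            response="no_response", rt=np.nan,
        ))
        i += 1
    return pd.DataFrame(rows)
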