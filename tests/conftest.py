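"""Shared fixtures: toy tables built by hand and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mmtraj as m


def events_frame(rows):
    """Build an events table from (person_id, condition, onset_time) tuples."""
    return pd.DataFrame(rows, columns=["person_id", "condition", "onset_time"])


def persons_frame(ids, censor_time=9.0, gender="F", age_band="45-54"):
    return pd.DataFrame(
        {
            "person_id": list(ids),
            "gender": [gender] * len(ids),
            "age_band": [age_band] * len(ids),
            "censor_time": [censor_time] * len(ids),
        }
    )


def traj_from_events(rows, tie_rule="canonical"):
    return m.assign_ranks(events_frame(rows), tie_rule=tie_rule)


@pytest.fixture(scope="session")
def null_cohort():
    """Screened cohort under the global null (no progression, no covariates)."""
    spec = m.CohortSpec(n_persons=4000)
    persons, events = m.simulate_screened_cohort(spec, m.null_hazard_spec(), seed=11)
    return persons, events


@pytest.fixture(scope="session")
def accelerated_cohort():
    """Screened cohort with uniform progression multiplier 2 and covariates."""
    spec = m.CohortSpec(n_persons=6000)
    persons, events = m.simulate_screened_cohort(
        spec, m.default_hazard_spec(progression=2.0), seed=12
    )
    return persons, events


@pytest.fixture(scope="session")
def accelerated_traj(accelerated_cohort):
    persons, events = accelerated_cohort
    return persons, m.assign_ranks(events)
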