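"""Shared fixtures: small generated trials and hand-built long tables."""

import numpy as np
import pandas as pd
import pytest

from trialcea import TrialConfig, TrialDataset, UnitCostTable, generate_trial
from trialcea.dataset import PERIODS, SCHEMA


@pytest.fixture(scope="session")
def prices() -> UnitCostTable:
    return UnitCostTable()


@pytest.fixture(scope="session")
def small_trial() -> TrialDataset:
    """A complete (no-dropout) trial of 20 participants per arm."""
    return generate_trial(TrialConfig(n_per_arm=20, seed=11))


def _default_row(pid, arm, period):
    return {
        "id": pid,
        "period": period,
        "arm": arm,
        "gender": "male",
        "age": 40.0,
        "non_dutch": 0,
        "education": 1,
        "safety_behavior": 20.0,
        "paid_work": 0,
        "hospital_days": 0,
        "psychiatrist_visits": 0,
        "nurse_visits": 0,
        "psychologist_sessions": 0,
        "vr_sessions": 0,
        "rx_antipsychotic_price": 0.0,
        "rx_antipsychotic_days": 0,
        "rx_antipsychotic_first": 0,
        "rx_antidepressant_price": 0.0,
        "rx_antidepressant_days": 0,
        "rx_antidepressant_first": 0,
        "health_visits": 0,
        "sick_leave_days": 0,
        "contract_hours_per_week": 0.0,
        "gpts": 50.0,
        "time_with_others": 0.5,
        "momentary_anxiety": 3.0,
        "momentary_paranoia": 3.0,
        "missing": 0,
    }


def build_outcome_trial(outcome: str, treat_pairs, ctrl_pairs) -> TrialDataset:
    """A trial where ``outcome`` takes given (baseline, followup) values.

    ``treat_pairs`` / ``ctrl_pairs`` are sequences of (baseline, followup)
    tuples, one per participant; every other column is a harmless constant.
    """
    rows = []
    pid = 0
    for arm, pairs in (("VR-CBT", treat_pairs), ("TAU", ctrl_pairs)):
        for baseline, followup in pairs:
            for period in PERIODS:
                row = _default_row(pid, arm, period)
                row[outcome] = followup if period == "followup" else baseline
                rows.append(row)
            pid += 1
    df = pd.DataFrame(rows, columns=list(SCHEMA))
    return TrialDataset(df)


def responder_pairs(n_resp: int, n_total: int, outcome: str = "momentary_paranoia"):
    """(baseline, followup) pairs yielding exactly n_resp responders.

    Uses a 25% improvement for responders and no change otherwise (both
    symmetric under the 20%-improvement rule for any direction)."""
    if outcome == "time_with_others":
        resp, non = (0.4, 0.5), (0.4, 0.4)
    else:
        resp, non = (4.0, 3.0), (4.0, 4.0)
    return [resp] * n_resp + [non] * (n_total - n_resp)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
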