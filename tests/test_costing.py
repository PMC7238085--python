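"""Costing rules: worked examples, invariants, and an independent
line-by-line oracle."""

import math
from decimal import Decimal, ROUND_HALF_UP

import pytest
from hypothesis import given, settings, strategies as st

from trialcea import (
    ParameterError,
    Prescription,
    ResourceUse,
    UnitCostTable,
    UnknownServiceError,
    cost_health_services,
    cost_medication,
    cost_period,
    cost_productivity,
    cost_travel,
    index_costs,
    societal_costs,
)

PRICES = UnitCostTable()


# ---------------------------------------------------------------------------
# medication
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "prescriptions, expected",
    [
        ([], 0.0),
        # 90 days at EUR 1/day, ongoing: 90 + 3 monthly dispensings x EUR 6
        ([Prescription("antipsychotic", 1.0, 90)], 108.0),
        # first-time, 30 days, free drug: only the EUR 12 first dispensing
        ([Prescription("antidepressant", 0.0, 30, first_time=True)], 12.0),
        # first-time 60 days: EUR 12 first month + EUR 6 second
        ([Prescription("antipsychotic", 0.5, 60, first_time=True)], 30.0 + 18.0),
        ([Prescription("antipsychotic", 2.0, 0)], 0.0),  # no days, no dispensing
    ],
)
def test_medication_cost_examples(prescriptions, expected):
    assert cost_medication(prescriptions, PRICES) == pytest.approx(expected, abs=1e-9)


def test_medication_negative_days_rejected():
    with pytest.raises(ParameterError):
        cost_medication([Prescription("antipsychotic", 1.0, -1)], PRICES)


# ---------------------------------------------------------------------------
# health services / travel / productivity / indexing
# ---------------------------------------------------------------------------

def test_empty_resource_use_costs_nothing():
    use = ResourceUse()
    assert cost_health_services(use, PRICES) == 0.0
    assert cost_travel(use, PRICES) == 0.0
    assert cost_productivity(use, "male", PRICES) == 0.0


def test_vr_course_cost_charged_once_per_treated_patient():
    use = ResourceUse(vr_sessions_attended=16)
    assert cost_health_services(use, PRICES) == pytest.approx(373.95)
    # partial attendance still incurs the full course by default
    assert cost_health_services(ResourceUse(vr_sessions_attended=3), PRICES) == pytest.approx(373.95)
    prorated = UnitCostTable(vr_prorate=True)
    assert cost_health_services(ResourceUse(vr_sessions_attended=8), prorated) == pytest.approx(
        373.95 / 2, abs=0.01
    )


def test_health_services_hand_sum():
    # 3 hospital days + 2 psychiatrist sessions + one 30-day prescription
    use = ResourceUse(
        service_contacts={"hospital_day": 3, "psychiatrist_visit": 2},
        prescriptions=[Prescription("antipsychotic", 1.5, 30)],
    )
    p = PRICES.price_per_service_unit
    expected = 3 * p["hospital_day"] + 2 * p["psychiatrist_visit"] + (30 * 1.5 + 6)
    assert cost_health_services(use, PRICES) == pytest.approx(expected, abs=1e-9)


def test_unknown_service_type_names_missing_price():
    use = ResourceUse(service_contacts={"acupuncture": 1})
    with pytest.raises(UnknownServiceError, match="acupuncture"):
        cost_health_services(use, PRICES)


@pytest.mark.parametrize("visits, expected", [(0, 0.0), (1, 2.94), (10, 29.40)])
def test_travel_cost_per_return_trip(visits, expected):
    use = ResourceUse(health_visits=visits)
    assert cost_travel(use, PRICES) == pytest.approx(expected, abs=1e-9)


def test_productivity_human_capital_examples():
    rate30 = UnitCostTable(hourly_productivity={"male": 30.0, "female": 30.0})
    # 5 sick days on a 40 h/week contract at EUR 30/h: 5 x 8 x 30
    use = ResourceUse(sick_leave_days=5, contract_hours_per_week=40.0)
    assert cost_productivity(use, "male", rate30) == pytest.approx(1200.0)
    # contract reduced from 40 to 20 h/week, no sick days: 20 h x 13 weeks
    use = ResourceUse(contract_hours_per_week=20.0, contract_hours_reduction=20.0)
    assert cost_productivity(use, "female", rate30) == pytest.approx(20 * 13 * 30.0)
    # without paid work, losses are zero regardless of recorded fields
    assert cost_productivity(use, "male", rate30, paid_work=False) == 0.0


def test_productivity_unknown_gender_rate():
    with pytest.raises(ParameterError, match="gender"):
        cost_productivity(ResourceUse(sick_leave_days=1), "other", PRICES)


@pytest.mark.parametrize(
    "amount, factor, expected", [(123.45, 1.0, 123.45), (100.0, 1.006, 100.60), (0.0, 2.5, 0.0)]
)
def test_cpi_indexing(amount, factor, expected):
    assert index_costs(amount, factor) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

counts = st.integers(min_value=0, max_value=20)


@st.composite
def resource_uses(draw):
    services = {
        name: draw(counts)
        for name in ("hospital_day", "psychiatrist_visit", "nurse_visit", "psychologist_session")
    }
    rxs = [
        Prescription(
            "antipsychotic",
            daily_dose_price=draw(st.integers(0, 500)) / 100.0,
            days=draw(st.integers(0, 120)),
            first_time=draw(st.booleans()),
        )
        for _ in range(draw(st.integers(0, 2)))
    ]
    return ResourceUse(
        service_contacts=services,
        prescriptions=rxs,
        health_visits=draw(counts),
        sick_leave_days=draw(st.integers(0, 30)),
        contract_hours_per_week=draw(st.integers(0, 40)),
        contract_hours_reduction=draw(st.integers(0, 16)),
        vr_sessions_attended=draw(st.integers(0, 16)),
    )


@given(use=resource_uses(), gender=st.sampled_from(["male", "female"]))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_breakdown_additive_to_the_cent(use, gender):
    b = cost_period(use, gender, PRICES)
    total_cents = round(b.total_societal * 100)
    parts_cents = round(b.health_care * 100) + round(b.travel * 100) + round(b.productivity * 100)
    assert total_cents == parts_cents


@given(use=resource_uses())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_doubling_service_units_doubles_service_costs(use):
    """Homogeneity of the per-unit components (service contacts, travel)."""
    base = ResourceUse(service_contacts=use.service_contacts, health_visits=use.health_visits)
    doubled = ResourceUse(
        service_contacts={k: 2 * v for k, v in use.service_contacts.items()},
        health_visits=2 * use.health_visits,
    )
    assert cost_health_services(doubled, PRICES) == pytest.approx(
        2 * cost_health_services(base, PRICES), abs=1e-9
    )
    assert cost_travel(doubled, PRICES) == pytest.approx(2 * cost_travel(base, PRICES), abs=1e-9)


@given(use=resource_uses(), gender=st.sampled_from(["male", "female"]))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_adding_resource_units_never_decreases_costs(use, gender):
    before = cost_period(use, gender, PRICES)
    bumped = ResourceUse(
        service_contacts={**use.service_contacts, "hospital_day": use.service_contacts["hospital_day"] + 1},
        prescriptions=use.prescriptions,
        health_visits=use.health_visits + 1,
        sick_leave_days=use.sick_leave_days + 1,
        contract_hours_per_week=use.contract_hours_per_week,
        contract_hours_reduction=use.contract_hours_reduction,
        vr_sessions_attended=use.vr_sessions_attended,
    )
    after = cost_period(bumped, gender, PRICES)
    assert after.health_care >= before.health_care
    assert after.travel >= before.travel
    assert after.productivity >= before.productivity
    assert after.total_societal >= before.total_societal


# ---------------------------------------------------------------------------
# independent spreadsheet-style oracle
# ---------------------------------------------------------------------------

def _oracle_costs(use: ResourceUse, gender: str, prices: UnitCostTable):
    """Line-by-line Decimal re-computation of the costing rules."""

    def cents(x):
        return Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)

    health = Decimal("0")
    for service, count in use.service_contacts.items():
        health += cents(count * prices.price_per_service_unit[service])
    for rx in use.prescriptions:
        health += cents(rx.daily_dose_price * rx.days)
        months = math.ceil(rx.days / 30)
        if months:
            first = prices.dispensing_first if rx.first_time else prices.dispensing_monthly
            health += cents(first + (months - 1) * prices.dispensing_monthly)
    if use.vr_sessions_attended > 0:
        course = prices.vr_per_patient_course
        if prices.vr_prorate:
            course = course * use.vr_sessions_attended / 16
        health += cents(course)
    travel = cents(use.health_visits * 2 * prices.travel_km * prices.cost_per_km)
    hours = use.sick_leave_days * use.contract_hours_per_week / 5
    hours += use.contract_hours_reduction * 13
    productivity = cents(hours * prices.hourly_productivity[gender])
    return float(health), float(travel), float(productivity)


def test_costing_matches_independent_oracle(rng):
    """20 random small resource-use instances agree to the cent."""
    for _ in range(20):
        use = ResourceUse(
            service_contacts={
                "hospital_day": int(rng.integers(0, 10)),
                "psychiatrist_visit": int(rng.integers(0, 6)),
                "nurse_visit": int(rng.integers(0, 12)),
                "psychologist_session": int(rng.integers(0, 6)),
            },
            prescriptions=[
                Prescription(
                    "antipsychotic",
                    daily_dose_price=int(rng.integers(0, 400)) / 100.0,
                    days=int(rng.integers(0, 95)),
                    first_time=bool(rng.integers(0, 2)),
                )
            ],
            health_visits=int(rng.integers(0, 25)),
            sick_leave_days=int(rng.integers(0, 20)),
            contract_hours_per_week=int(rng.integers(0, 41)),
            contract_hours_reduction=int(rng.integers(0, 10)),
            vr_sessions_attended=int(rng.integers(0, 17)),
        )
        gender = "male" if rng.integers(0, 2) else "female"
        health, travel, productivity = _oracle_costs(use, gender, PRICES)
        assert cost_health_services(use, PRICES) == pytest.approx(health, abs=0.005)
        assert cost_travel(use, PRICES) == pytest.approx(travel, abs=0.005)
        assert cost_productivity(use, gender, PRICES) == pytest.approx(productivity, abs=0.005)


# ---------------------------------------------------------------------------
# participant-level aggregation
# ---------------------------------------------------------------------------

def test_cumulative_excludes_baseline(small_trial, prices):
    participant = next(small_trial.participants())
    costs = societal_costs(participant, prices)
    cum = costs["cumulative"]
    expected = costs["post"] + costs["followup"]
    assert cum.health_care == expected.health_care
    assert cum.total_societal == expected.total_societal
    # baseline contributes nothing to the cumulative figure
    assert cum.total_societal != pytest.approx(
        (costs["baseline"] + expected).total_societal
    ) or costs["baseline"].total_societal == 0


def test_all_zero_resource_use_gives_zero_breakdown():
    use = ResourceUse(service_contacts={"hospital_day": 0})
    b = cost_period(use, "female", PRICES)
    assert (b.health_care, b.travel, b.productivity, b.total_societal) == (0, 0, 0, 0)
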