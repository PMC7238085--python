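"""Societal-perspective costing of per-period resource use.

Societal costs per participant-period are the sum of three components:

1. direct medical costs — health-service contacts (sessions, visits,
   hospital days) priced at standard economic unit costs, plus medication
   (standard-daily-dose price x prescription days + pharmacist dispensing
   fees), plus the per-patient virtual-reality therapy course cost in the
   treated arm;
2. direct nonmedical costs of travel — return trips to health services;
3. indirect costs of lost productivity, valued by the human capital
   approach with gender-specific hourly productivity rates.

All arithmetic is carried out in integer cents (round-half-up) so that the
component/total additivity holds to the cent, and amounts are indexed to
the reference price year with a consumer-price-index factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

from .dataset import Participant, Prescription, ResourceUse
from .errors import ParameterError, UnknownServiceError

WORKING_DAYS_PER_WEEK = 5
WEEKS_PER_PERIOD = 13.0  # one 3-month costing period
DAYS_PER_DISPENSING_MONTH = 30
MAX_VR_SESSIONS = 16


def _cents(amount: float) -> int:
    """EUR -> integer cents, rounding half-up (ties away from zero for >=0)."""
    return int(math.floor(amount * 100.0 + 0.5))


def _eur(cents: int) -> float:
    return cents / 100.0


@dataclass
class UnitCostTable:
    """Unit prices and costing constants (societal perspective).

    Default service prices and productivity rates follow Dutch
    costing-manual conventions for the 2014 reference year; everything is
    configuration, nothing is hard-coded in the costing rules.  The CPI
    factor indexes 2014 prices to the 2015 reporting year.
    """

    price_per_service_unit: dict[str, float] = field(
        default_factory=lambda: {
            "hospital_day": 255.0,
            "psychiatrist_visit": 96.0,
            "nurse_visit": 65.0,
            "psychologist_session": 94.0,
            "vr_cbt_session": 116.0,
        }
    )
    travel_km: float = 7.0
    cost_per_km: float = 0.21
    dispensing_monthly: float = 6.0
    dispensing_first: float = 12.0
    vr_per_patient_course: float = 373.95
    vr_prorate: bool = False
    hourly_productivity: dict[str, float] = field(
        default_factory=lambda: {"male": 34.75, "female": 26.36}
    )
    cpi_factor: float = 1.006

    def __post_init__(self):
        for key, price in self.price_per_service_unit.items():
            if price < 0:
                raise ParameterError(f"price_per_service_unit[{key!r}] must be >= 0")
        for name in (
            "travel_km",
            "cost_per_km",
            "dispensing_monthly",
            "dispensing_first",
            "vr_per_patient_course",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for key, rate in self.hourly_productivity.items():
            if rate < 0:
                raise ParameterError(f"hourly_productivity[{key!r}] must be >= 0")
        if self.cpi_factor <= 0:
            raise ParameterError("cpi_factor must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-period societal costs in EUR, additive to the cent."""

    health_care: float
    travel: float
    productivity: float

    @property
    def total_societal(self) -> float:
        return _eur(_cents(self.health_care) + _cents(self.travel) + _cents(self.productivity))

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            _eur(_cents(self.health_care) + _cents(other.health_care)),
            _eur(_cents(self.travel) + _cents(other.travel)),
            _eur(_cents(self.productivity) + _cents(other.productivity)),
        )


def cost_medication(prescriptions: list[Prescription], prices: UnitCostTable) -> float:
    """Medication cost: daily-dose price x days plus dispensing fees.

    A prescription spanning d days incurs ceil(d / 30) monthly dispensings;
    a first-time prescription pays the higher first fee for its first month
    and the regular monthly fee thereafter.
    """
    total = 0
    for rx in prescriptions:
        if rx.days < 0:
            raise ParameterError(f"prescription days must be >= 0, got {rx.days}")
        if rx.daily_dose_price < 0:
            raise ParameterError("daily_dose_price must be >= 0")
        total += _cents(rx.daily_dose_price * rx.days)
        months = math.ceil(rx.days / DAYS_PER_DISPENSING_MONTH)
        if months > 0:
            if rx.first_time:
                fee = prices.dispensing_first + prices.dispensing_monthly * (months - 1)
            else:
                fee = prices.dispensing_monthly * months
            total += _cents(fee)
    return _eur(total)


def cost_health_services(use: ResourceUse, prices: UnitCostTable) -> float:
    """Direct medical costs: service units x unit price + medication + VR course.

    The VR therapy course cost is charged once per patient with any
    attended session (full course price by default; pro-rated by attended
    sessions out of 16 when ``prices.vr_prorate`` is set).
    """
    missing = set(use.service_contacts) - set(prices.price_per_service_unit)
    if missing:
        raise UnknownServiceError(missing)
    if use.vr_sessions_attended > MAX_VR_SESSIONS:
        raise ParameterError(
            f"vr_sessions_attended must be <= {MAX_VR_SESSIONS}, got {use.vr_sessions_attended}"
        )
    total = 0
    for service, count in use.service_contacts.items():
        if count < 0:
            raise ParameterError(f"service count for {service!r} must be >= 0")
        total += _cents(count * prices.price_per_service_unit[service])
    total += _cents(cost_medication(use.prescriptions, prices))
    if use.vr_sessions_attended > 0:
        course = prices.vr_per_patient_course
        if prices.vr_prorate:
            course *= use.vr_sessions_attended / MAX_VR_SESSIONS
        total += _cents(course)
    return _eur(total)


def cost_travel(use: ResourceUse, prices: UnitCostTable) -> float:
    """Travel costs: return trips x 2 x one-way distance x cost per km."""
    if use.health_visits < 0:
        raise ParameterError("health_visits must be >= 0")
    round_trip_km = 2.0 * prices.travel_km
    return _eur(_cents(use.health_visits * round_trip_km * prices.cost_per_km))


def cost_productivity(
    use: ResourceUse,
    gender: str,
    prices: UnitCostTable,
    *,
    paid_work: bool = True,
    weeks_in_period: float = WEEKS_PER_PERIOD,
) -> float:
    """Indirect costs by the human capital approach.

    Lost hours are sick-leave days converted at contract hours / 5-day
    working week, plus any contractual-hours reduction relative to baseline
    accumulated over the period; both are valued at the gender-specific
    hourly productivity rate.  Participants without paid work incur zero
    productivity losses.
    """
    if not paid_work:
        return 0.0
    if gender not in prices.hourly_productivity:
        raise ParameterError(
            f"no hourly productivity rate for gender {gender!r}; "
            f"known: {sorted(prices.hourly_productivity)}"
        )
    if use.sick_leave_days < 0:
        raise ParameterError("sick_leave_days must be >= 0")
    rate = prices.hourly_productivity[gender]
    hours_per_day = use.contract_hours_per_week / WORKING_DAYS_PER_WEEK
    lost_hours = use.sick_leave_days * hours_per_day
    lost_hours += max(0.0, use.contract_hours_reduction) * weeks_in_period
    return _eur(_cents(lost_hours * rate))


def index_costs(amount: float, factor: float) -> float:
    """Index an amount to the reporting price year by a CPI ratio."""
    if factor <= 0:
        raise ParameterError("cpi factor must be > 0")
    return _eur(_cents(amount * factor))


def cost_period(
    use: ResourceUse,
    gender: str,
    prices: UnitCostTable,
    *,
    paid_work: bool = True,
    index: bool = True,
) -> CostBreakdown:
    """Cost one participant-period; components CPI-indexed individually."""
    health = cost_health_services(use, prices)
    travel = cost_travel(use, prices)
    prod = cost_productivity(use, gender, prices, paid_work=paid_work)
    if index:
        health = index_costs(health, prices.cpi_factor)
        travel = index_costs(travel, prices.cpi_factor)
        prod = index_costs(prod, prices.cpi_factor)
    return CostBreakdown(health, travel, prod)


def cumulate(period_costs: dict[str, CostBreakdown]) -> CostBreakdown:
    """Cumulative costs over the trial: posttreatment + follow-up periods.

    Baseline costs are deliberately excluded — they describe the pre-trial
    state and enter the analysis only as adjustment covariates.
    """
    return period_costs["post"] + period_costs["followup"]


def societal_costs(
    participant: Participant, prices: UnitCostTable, *, index: bool = True
) -> dict[str, CostBreakdown]:
    """Per-period cost breakdowns plus the ``cumulative`` breakdown.

    Requires costed (non-missing) resource use in every period; run the
    imputation stage first on incomplete data.
    """
    out: dict[str, CostBreakdown] = {}
    for period, record in participant.periods.items():
        if record.resource_use is None:
            raise ParameterError(
                f"participant {participant.id!r} has no resource use in period "
                f"{period!r}; impute before costing"
            )
        out[period] = cost_period(
            record.resource_use,
            participant.gender,
            prices,
            paid_work=participant.paid_work,
            index=index,
        )
    out["cumulative"] = cumulate(out)
    return out
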