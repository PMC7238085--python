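"""Trial data containers and long-format CSV round trip.

The canonical in-memory representation of a trial is a long-format
:class:`pandas.DataFrame` wrapped by :class:`TrialDataset`: one row per
participant-period, three fixed periods per participant (``baseline``,
``post`` — the 3-month posttreatment assessment — and ``followup`` at
6 months).  Resource use is stored as flat count/price columns; the
object view (:class:`Participant` / :class:`PeriodRecord`) is derived on
demand for the per-participant costing API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError

ARMS = ("VR-CBT", "TAU")
PERIODS = ("baseline", "post", "followup")

#: participant-level columns, constant across a participant's three rows
BASELINE_COLUMNS = (
    "arm",
    "gender",
    "age",
    "non_dutch",
    "education",
    "safety_behavior",
    "paid_work",
)

#: per-period resource-use columns (all counts/prices, >= 0)
RESOURCE_COLUMNS = (
    "hospital_days",
    "psychiatrist_visits",
    "nurse_visits",
    "psychologist_sessions",
    "vr_sessions",
    "rx_antipsychotic_price",
    "rx_antipsychotic_days",
    "rx_antipsychotic_first",
    "rx_antidepressant_price",
    "rx_antidepressant_days",
    "rx_antidepressant_first",
    "health_visits",
    "sick_leave_days",
    "contract_hours_per_week",
)

#: per-period clinical / experience-sampling outcome columns
OUTCOME_COLUMNS = ("gpts", "time_with_others", "momentary_anxiety", "momentary_paranoia")

SCHEMA = ("id", "period") + BASELINE_COLUMNS + RESOURCE_COLUMNS + OUTCOME_COLUMNS + ("missing",)


@dataclass(frozen=True)
class Prescription:
    """One medication prescription over a 3-month period.

    ``daily_dose_price`` is the cost of one standard daily dose in EUR;
    ``first_time`` marks a first-ever prescription, which carries a higher
    initial pharmacist dispensing fee.
    """

    drug_class: str
    daily_dose_price: float
    days: int
    first_time: bool = False


@dataclass
class ResourceUse:
    """Resource use of one participant over one 3-month period."""

    service_contacts: dict[str, float] = field(default_factory=dict)
    prescriptions: list[Prescription] = field(default_factory=list)
    health_visits: float = 0.0
    sick_leave_days: float = 0.0
    contract_hours_per_week: float = 0.0
    contract_hours_reduction: float = 0.0
    vr_sessions_attended: float = 0.0


@dataclass
class PeriodRecord:
    resource_use: ResourceUse | None
    gpts: float | None
    time_with_others: float | None
    momentary_anxiety: float | None
    momentary_paranoia: float | None
    missing: bool = False


@dataclass
class Participant:
    id: object
    arm: str
    gender: str
    age: float
    non_dutch: bool
    education: int
    safety_behavior: float
    paid_work: bool
    periods: dict[str, PeriodRecord]


def _row_to_resource_use(row: Mapping, baseline_hours: float) -> ResourceUse:
    contacts = {
        "hospital_day": row["hospital_days"],
        "psychiatrist_visit": row["psychiatrist_visits"],
        "nurse_visit": row["nurse_visits"],
        "psychologist_session": row["psychologist_sessions"],
        # therapist time of attended VR-CBT sessions is a priced service
        # contact; the per-course equipment cost rides on vr_sessions_attended
        "vr_cbt_session": row["vr_sessions"],
    }
    prescriptions = []
    for drug in ("antipsychotic", "antidepressant"):
        days = row[f"rx_{drug}_days"]
        if days and days > 0:
            prescriptions.append(
                Prescription(
                    drug_class=drug,
                    daily_dose_price=float(row[f"rx_{drug}_price"]),
                    days=int(days),
                    first_time=bool(row[f"rx_{drug}_first"]),
                )
            )
    hours = float(row["contract_hours_per_week"])
    return ResourceUse(
        service_contacts={k: float(v) for k, v in contacts.items()},
        prescriptions=prescriptions,
        health_visits=float(row["health_visits"]),
        sick_leave_days=float(row["sick_leave_days"]),
        contract_hours_per_week=hours,
        contract_hours_reduction=max(0.0, baseline_hours - hours),
        vr_sessions_attended=float(row["vr_sessions"]),
    )


class TrialDataset:
    """Long-format trial table with three fixed periods per participant."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- container basics -------------------------------------------------
    def __len__(self) -> int:
        return self.df["id"].nunique()

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy(), validate=False)

    def n_per_arm(self) -> dict[str, int]:
        base = self.df[self.df["period"] == "baseline"]
        return base.groupby("arm")["id"].nunique().to_dict()

    def validate(self) -> None:
        df = self.df
        unknown = set(df.columns) - set(SCHEMA)
        if unknown:
            raise SchemaError(f"unknown column(s): {sorted(unknown)}")
        missing_cols = set(SCHEMA) - set(df.columns)
        if missing_cols:
            raise SchemaError(f"missing column(s): {sorted(missing_cols)}")
        if df.empty:
            return
        bad_arm = set(df["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise SchemaError(f"unknown arm label(s): {sorted(bad_arm)}")
        bad_period = set(df["period"].unique()) - set(PERIODS)
        if bad_period:
            raise SchemaError(f"unknown period label(s): {sorted(bad_period)}")
        counts = df.groupby("id")["period"].count()
        if (counts != 3).any():
            bad = counts[counts != 3].index.tolist()[:5]
            raise SchemaError(f"participants without exactly 3 periods: {bad}")
        if (df.groupby("id")["arm"].nunique() != 1).any():
            raise SchemaError("arm assignment changes over time for some participant")
        obs = df[df["missing"].fillna(0).astype(float) == 0]
        for col, lo, hi in (
            ("time_with_others", 0.0, 1.0),
            ("momentary_anxiety", 1.0, 7.0),
            ("momentary_paranoia", 1.0, 7.0),
        ):
            vals = obs[col].dropna()
            if len(vals) and ((vals < lo) | (vals > hi)).any():
                raise SchemaError(f"{col} outside [{lo}, {hi}]")
        for col in RESOURCE_COLUMNS:
            vals = obs[col].dropna()
            if len(vals) and (vals < 0).any():
                raise SchemaError(f"negative values in {col}")

    # -- object view -------------------------------------------------------
    def participants(self) -> Iterator[Participant]:
        for pid, grp in self.df.groupby("id", sort=False):
            grp = grp.set_index("period").loc[list(PERIODS)]
            base = grp.loc["baseline"]
            bl_hours = float(base["contract_hours_per_week"]) if np.isfinite(
                base["contract_hours_per_week"]
            ) else 0.0
            periods = {}
            for period in PERIODS:
                row = grp.loc[period]
                is_missing = bool(row["missing"]) if not pd.isna(row["missing"]) else False
                if is_missing or pd.isna(row["hospital_days"]):
                    use = None
                else:
                    use = _row_to_resource_use(row, bl_hours)
                periods[period] = PeriodRecord(
                    resource_use=use,
                    gpts=None if pd.isna(row["gpts"]) else float(row["gpts"]),
                    time_with_others=None
                    if pd.isna(row["time_with_others"])
                    else float(row["time_with_others"]),
                    momentary_anxiety=None
                    if pd.isna(row["momentary_anxiety"])
                    else float(row["momentary_anxiety"]),
                    momentary_paranoia=None
                    if pd.isna(row["momentary_paranoia"])
                    else float(row["momentary_paranoia"]),
                    missing=is_missing,
                )
            yield Participant(
                id=pid,
                arm=str(base["arm"]),
                gender=str(base["gender"]),
                age=float(base["age"]),
                non_dutch=bool(base["non_dutch"]),
                education=int(base["education"]),
                safety_behavior=float(base["safety_behavior"]),
                paid_work=bool(base["paid_work"]),
                periods=periods,
            )


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write the long-format table; missing cells become empty fields."""
    df = dataset.df.loc[:, list(SCHEMA)]
    df.to_csv(path, index=False, na_rep="")


def read_trial_csv(path) -> TrialDataset:
    """Read and validate a long-format trial CSV.

    Raises :class:`SchemaError` naming any unknown or absent column; an
    empty-but-headered file yields an empty dataset.
    """
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(SCHEMA)
    if unknown:
        raise SchemaError(f"unknown column(s): {sorted(unknown)}")
    missing_cols = set(SCHEMA) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"missing column(s): {sorted(missing_cols)}")
    return TrialDataset(df)
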