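"""Effect measures: social-participation responders and QALY mapping.

The cost-effectiveness analysis uses three experience-sampling measures of
social participation (time spent with others, momentary anxiety, momentary
paranoia); a treatment responder improves by at least 20% at 6-month
follow-up relative to their own baseline.  The cost-utility analysis maps
the between-arm standardized mean difference (SMD) of the paranoid-ideation
scale (GPTS) change onto utility with the Sanderson conversion factor
(0.1835 utility per SMD unit) over the half-year horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import TrialDataset
from .errors import ParameterError

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    direction: str
    response_threshold: float = 0.20

    def __post_init__(self):
        if not 0.0 < self.response_threshold < 1.0:
            raise ParameterError("response_threshold must be in (0, 1)")
        if self.direction not in (HIGHER_IS_BETTER, LOWER_IS_BETTER):
            raise ParameterError(f"unknown direction {self.direction!r}")


#: the study's outcome definitions
OUTCOME_SPECS = {
    "time_with_others": OutcomeSpec("time_with_others", HIGHER_IS_BETTER),
    "momentary_anxiety": OutcomeSpec("momentary_anxiety", LOWER_IS_BETTER),
    "momentary_paranoia": OutcomeSpec("momentary_paranoia", LOWER_IS_BETTER),
    "gpts": OutcomeSpec("gpts", LOWER_IS_BETTER),
}


@dataclass(frozen=True)
class UtilityMapping:
    """SMD -> utility conversion and QALY horizon.

    The default factor 0.1835 is the average of rating-scale (0.209) and
    time-trade-off (0.158) valuations of one standardized unit of symptom
    change; the default horizon is the 6-month trial window.
    """

    conversion_factor: float = 0.1835
    horizon_years: float = 0.5

    def __post_init__(self):
        if self.conversion_factor <= 0:
            raise ParameterError("conversion_factor must be > 0")
        if self.horizon_years <= 0:
            raise ParameterError("horizon_years must be > 0")


def relative_improvement(baseline: float, followup: float, spec: OutcomeSpec) -> float:
    """Signed relative change, positive for improvement; undefined at 0 baseline."""
    if baseline == 0:
        raise ZeroDivisionError("relative improvement undefined at zero baseline")
    if spec.direction == LOWER_IS_BETTER:
        return (baseline - followup) / baseline
    return (followup - baseline) / baseline


def classify_response(baseline: float, followup: float, spec: OutcomeSpec) -> bool:
    """Responder rule: relative improvement of at least the threshold (20%).

    The boundary counts as response ("at least 20%").  A zero baseline —
    possible only for the time-with-others proportion — is handled by the
    documented fallback: responder iff any follow-up improvement exists.
    """
    if baseline == 0:
        if spec.direction == HIGHER_IS_BETTER:
            return followup > 0
        return False  # symptom scales have a positive floor; defensive only
    return relative_improvement(baseline, followup, spec) >= spec.response_threshold


@dataclass(frozen=True)
class ResponseRates:
    rate_treat: float
    rate_ctrl: float
    n_treat: int
    n_ctrl: int

    @property
    def difference(self) -> float:
        return self.rate_treat - self.rate_ctrl


def classify_dataset(dataset: TrialDataset, spec: OutcomeSpec) -> pd.DataFrame:
    """Per-participant responder flags for one outcome.

    Uses the 6-month follow-up value against baseline; requires complete
    (post-imputation) data for the outcome at both periods.
    """
    wide = dataset.df.pivot(index="id", columns="period", values=spec.name)
    arm = dataset.df[dataset.df["period"] == "baseline"].set_index("id")["arm"]
    if wide[["baseline", "followup"]].isna().any().any():
        raise ParameterError(
            f"missing {spec.name} values; impute before classifying responses"
        )
    flags = [
        classify_response(b, f, spec)
        for b, f in zip(wide["baseline"], wide["followup"])
    ]
    return pd.DataFrame(
        {
            "id": wide.index,
            "arm": arm.loc[wide.index].to_numpy(),
            "baseline": wide["baseline"].to_numpy(),
            "followup": wide["followup"].to_numpy(),
            "responder": np.asarray(flags, dtype=float),
        }
    )


def response_rates(dataset: TrialDataset, spec: OutcomeSpec) -> ResponseRates:
    """Per-arm responder proportions and their unadjusted difference.

    Covariate-adjusted differences with regression standard errors come
    from the estimation module; this is the raw contrast.
    """
    flags = classify_dataset(dataset, spec)
    out = {}
    for arm_label, key in (("VR-CBT", "treat"), ("TAU", "ctrl")):
        sub = flags[flags["arm"] == arm_label]
        if sub.empty:
            raise ParameterError(f"no participants in arm {arm_label!r}")
        out[key] = (sub["responder"].mean(), len(sub))
    return ResponseRates(
        rate_treat=out["treat"][0],
        rate_ctrl=out["ctrl"][0],
        n_treat=out["treat"][1],
        n_ctrl=out["ctrl"][1],
    )


def compute_smd(
    change_treat: float,
    change_ctrl: float,
    sd_ctrl_baseline: float,
    direction: str = LOWER_IS_BETTER,
) -> float:
    """Standardized mean difference of raw change scores.

    ``change_*`` are mean (follow-up - baseline) scores per arm; the result
    is divided by the control-arm baseline SD and signed so that an
    improvement in the treated arm is positive (for a symptom scale, a
    larger score *decrease* in the treated arm gives a positive SMD).
    """
    if sd_ctrl_baseline <= 0:
        raise ParameterError("sd_ctrl_baseline must be > 0")
    smd = (change_treat - change_ctrl) / sd_ctrl_baseline
    if direction == LOWER_IS_BETTER:
        smd = -smd
    return smd


def map_smd_to_qaly(smd: float, mapping: UtilityMapping = UtilityMapping()) -> float:
    """QALY gain = SMD x conversion factor x horizon (linear mapping)."""
    return smd * mapping.conversion_factor * mapping.horizon_years


def qaly_per_patient(
    baseline: np.ndarray,
    followup: np.ndarray,
    sd_ctrl_baseline: float,
    mapping: UtilityMapping = UtilityMapping(),
    direction: str = LOWER_IS_BETTER,
) -> np.ndarray:
    """Participant-level QALY contributions.

    Standardizes each participant's own change score by the (fixed)
    control-arm baseline SD and applies the utility mapping, so that the
    between-arm difference in means of this quantity equals the group-level
    SMD-mapped QALY gain.  This per-patient construction is what allows the
    QALY to enter the joint cost-effect regression and the bootstrap.
    """
    if sd_ctrl_baseline <= 0:
        raise ParameterError("sd_ctrl_baseline must be > 0")
    change = np.asarray(followup, dtype=float) - np.asarray(baseline, dtype=float)
    improvement = -change if direction == LOWER_IS_BETTER else change
    return improvement / sd_ctrl_baseline * mapping.conversion_factor * mapping.horizon_years
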