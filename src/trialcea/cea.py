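"""Bootstrap cost-effectiveness inference.

The joint sampling distribution of (incremental cost, incremental effect)
is obtained by nonparametric bootstrap: participants are resampled with
replacement, stratified by arm so every resample preserves the n/n
randomization ratio, and the SUR system is refit on each resample.  The
draws populate the cost-effectiveness plane, summarize into quadrant
proportions, and yield the cost-effectiveness acceptability curve (CEAC):
for each willingness-to-pay ceiling lambda, the fraction of draws with
positive net monetary benefit lambda * dE - dC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    ParameterError,
    UnattainedCertaintyError,
    UndefinedICERError,
)
from .estimation import (
    RegressionSpec,
    TREATMENT_COLUMN,
    _design,
    _fit_sur_arrays,
    fit_sure,
)

logger = logging.getLogger(__name__)

#: default willingness-to-pay grid, EUR 0 to 100,000 in EUR 500 steps
#: (brackets the EUR 20,000-80,000 per-QALY range used in Dutch practice)
DEFAULT_WTP_GRID = tuple(range(0, 100_001, 500))

MAX_REDRAW_FACTOR = 10


@dataclass(frozen=True)
class BootstrapDistribution:
    """B paired (delta_cost, delta_effect) bootstrap draws."""

    draws: np.ndarray  # shape (B, 2): column 0 = delta_cost, column 1 = delta_effect
    seed: int
    outcome_name: str = ""

    @property
    def B(self) -> int:
        return len(self.draws)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.draws[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b": np.arange(self.B),
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
            }
        )


@dataclass(frozen=True)
class QuadrantSummary:
    """CE-plane mass per quadrant (proportions summing to 1).

    Boundary draws (a delta of exactly zero) count as cost-increasing /
    effect-positive, a fixed rule for a measure-zero tie."""

    ne: float
    se: float
    nw: float
    sw: float


@dataclass(frozen=True)
class CeacCurve:
    wtp_grid: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.probability})


def bootstrap_cea(
    df: pd.DataFrame,
    spec: RegressionSpec,
    B: int = 5000,
    seed: int = 0,
    outcome_name: str = "",
) -> BootstrapDistribution:
    """Bootstrap the SUR system on arm-stratified resamples.

    Degenerate resamples (rank-deficient or zero-variance) are redrawn, up
    to ``10 * B`` total attempts, with the redraw count logged.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    Xc, yc, names_c = _design(df, spec.cost_outcome, spec.cost_covariates)
    Xe, ye, _ = _design(df, spec.effect_outcome, spec.effect_covariates)
    arm = df[TREATMENT_COLUMN].to_numpy(dtype=float)
    idx_by_arm = [np.flatnonzero(arm == a) for a in (0.0, 1.0)]
    if any(len(ix) == 0 for ix in idx_by_arm):
        raise ParameterError("both arms must be present to bootstrap")
    rng = np.random.default_rng(seed)
    draws = np.empty((B, 2))
    redraws = 0
    b = 0
    attempts = 0
    while b < B:
        attempts += 1
        if attempts > MAX_REDRAW_FACTOR * B:
            raise DegenerateFitError(
                f"bootstrap aborted: {redraws} degenerate resamples in "
                f"{attempts} attempts"
            )
        idx = np.concatenate([rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_arm])
        try:
            dc, _, de, _, _ = _fit_sur_arrays(Xc[idx], yc[idx], Xe[idx], ye[idx])
        except (DegenerateFitError, np.linalg.LinAlgError):
            redraws += 1
            continue
        if not (np.isfinite(dc) and np.isfinite(de)):
            redraws += 1
            continue
        draws[b] = (dc, de)
        b += 1
    if redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", redraws)
    return BootstrapDistribution(draws=draws, seed=seed, outcome_name=outcome_name)


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio: delta_cost / delta_effect."""
    if delta_effect == 0:
        raise UndefinedICERError("ICER undefined for zero incremental effect")
    return delta_cost / delta_effect


def quadrants(dist: BootstrapDistribution) -> QuadrantSummary:
    """Proportion of bootstrap draws in each CE-plane quadrant."""
    dc, de = dist.delta_cost, dist.delta_effect
    north = dc >= 0
    east = de >= 0
    return QuadrantSummary(
        ne=float(np.mean(north & east)),
        se=float(np.mean(~north & east)),
        nw=float(np.mean(north & ~east)),
        sw=float(np.mean(~north & ~east)),
    )


def ceac(dist: BootstrapDistribution, wtp_grid=DEFAULT_WTP_GRID) -> CeacCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid.

    A draw is cost-effective at ceiling lambda iff its net monetary
    benefit lambda * delta_effect - delta_cost is strictly positive.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ParameterError("wtp_grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("wtp_grid must be strictly increasing")
    nmb = grid[None, :] * dist.delta_effect[:, None] - dist.delta_cost[:, None]
    return CeacCurve(wtp_grid=grid, probability=(nmb > 0).mean(axis=0))


def wtp_at_certainty(curve: CeacCurve, level: float) -> float:
    """Smallest grid ceiling with P(cost-effective) >= level.

    Raises :class:`UnattainedCertaintyError` if the curve never reaches the
    level on its grid."""
    if not 0.0 < level < 1.0:
        raise ParameterError("level must be in (0, 1)")
    hits = np.flatnonzero(curve.probability >= level)
    if hits.size == 0:
        raise UnattainedCertaintyError(
            f"acceptability never reaches {level:.0%} on the supplied grid "
            f"(max {curve.probability.max():.2%})"
        )
    return float(curve.wtp_grid[hits[0]])


#: the study's sensitivity scenarios: extra baseline covariates per scenario
DEFAULT_SCENARIOS = {
    "none": (),
    "safety": ("safety_behavior",),
    "admission": ("bl_admission_cost",),
    "both": ("safety_behavior", "bl_admission_cost"),
}


def run_sensitivity(
    df: pd.DataFrame,
    spec: RegressionSpec,
    scenarios: dict = None,
    outcome_name: str = "",
) -> pd.DataFrame:
    """Re-estimate the incremental cost, effect, and ICER per scenario.

    Each scenario appends its baseline covariates to both equations and
    reruns the identical estimation pipeline; the ``none`` scenario
    reproduces the main analysis exactly.
    """
    scenarios = DEFAULT_SCENARIOS if scenarios is None else scenarios
    rows = []
    for name, extra in scenarios.items():
        est = fit_sure(df, spec.with_extra_covariates(extra))
        try:
            ratio = icer(est.delta_cost, est.delta_effect)
        except UndefinedICERError:
            ratio = np.nan
        rows.append(
            {
                "scenario": name,
                "outcome": outcome_name,
                "delta_cost": est.delta_cost,
                "se_cost": est.se_cost,
                "delta_effect": est.delta_effect,
                "se_effect": est.se_effect,
                "icer": ratio,
            }
        )
    return pd.DataFrame(rows)


def incremental(mean_treat: float, mean_ctrl: float) -> float:
    """Between-group (treated minus control) difference of two summaries."""
    return mean_treat - mean_ctrl
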