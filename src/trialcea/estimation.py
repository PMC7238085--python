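"""Joint estimation of incremental costs and effects.

The incremental (between-arm) cost and effect are the treatment
coefficients of a two-equation seemingly-unrelated-regression (SUR)
system,

    cost_i   = a_c + d_c * treat_i + covariates + e_ci
    effect_i = a_e + d_e * treat_i + covariates + e_ei,

estimated by one-step feasible GLS: per-equation least squares gives the
residual covariance, which then weights the stacked system.  Allowing
correlated residuals acknowledges that costs and effects are measured on
the same individuals.  Responder (binary) effects use a linear probability
model, so d_e is the adjusted risk difference directly.  When both
equations share the same regressors the FGLS estimates coincide with
per-equation OLS (the classical SUR identity), which the tests exploit as
an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateFitError, ParameterError

TREATMENT_COLUMN = "arm01"


@dataclass(frozen=True)
class RegressionSpec:
    """Which columns form the cost and effect equations.

    The treatment indicator and an intercept are always included; the
    covariate lists are per equation because baseline adjustment differs
    (the effect equation is adjusted by the baseline value of its outcome,
    the cost equation by baseline costs)."""

    cost_outcome: str
    effect_outcome: str
    cost_covariates: tuple = ()
    effect_covariates: tuple = ()

    def with_extra_covariates(self, extra) -> "RegressionSpec":
        extra = tuple(extra)
        return RegressionSpec(
            self.cost_outcome,
            self.effect_outcome,
            tuple(self.cost_covariates) + extra,
            tuple(self.effect_covariates) + extra,
        )


@dataclass(frozen=True)
class IncrementalEstimate:
    delta_cost: float
    se_cost: float
    delta_effect: float
    se_effect: float
    residual_correlation: float
    n: int
    df: int


def _design(df: pd.DataFrame, outcome: str, covariates) -> tuple[np.ndarray, np.ndarray, list]:
    cols = [TREATMENT_COLUMN, *covariates]
    for col in (outcome, *cols):
        if col not in df.columns:
            raise ParameterError(f"column {col!r} not found in dataset")
        if df[col].isna().any():
            raise ParameterError(f"column {col!r} contains missing values; impute first")
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols])
    y = df[outcome].to_numpy(dtype=float)
    return X, y, ["const"] + cols


def _check_rank(X: np.ndarray, names: list, label: str) -> None:
    n, k = X.shape
    if n <= k:
        raise DegenerateFitError(
            f"{label} equation has n={n} observations for {k} parameters"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the columns most collinear with the rest
        suspects = [
            names[j]
            for j in range(1, k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise DegenerateFitError(
            f"rank-deficient {label} design matrix; collinear column(s): {suspects}"
        )


def _fit_sur_arrays(
    Xc: np.ndarray, yc: np.ndarray, Xe: np.ndarray, ye: np.ndarray
) -> tuple[float, float, float, float, float]:
    """One-step FGLS on the two-equation system; fast numpy path.

    Returns (delta_cost, se_cost, delta_effect, se_effect, rho) where the
    deltas are the coefficients of column 1 (the treatment indicator).
    Raises LinAlgError/DegenerateFitError on singular systems.
    """
    n = len(yc)
    bc, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    be, *_ = np.linalg.lstsq(Xe, ye, rcond=None)
    rc = yc - Xc @ bc
    re = ye - Xe @ be
    S = np.array(
        [[rc @ rc, rc @ re], [rc @ re, re @ re]], dtype=float
    ) / n
    if S[0, 0] <= 0 or S[1, 1] <= 0:
        raise DegenerateFitError("zero residual variance in one equation")
    W = np.linalg.inv(S)
    kc, ke = Xc.shape[1], Xe.shape[1]
    XtX = np.empty((kc + ke, kc + ke))
    XtX[:kc, :kc] = W[0, 0] * (Xc.T @ Xc)
    XtX[:kc, kc:] = W[0, 1] * (Xc.T @ Xe)
    XtX[kc:, :kc] = W[1, 0] * (Xe.T @ Xc)
    XtX[kc:, kc:] = W[1, 1] * (Xe.T @ Xe)
    Xty = np.concatenate(
        [
            W[0, 0] * (Xc.T @ yc) + W[0, 1] * (Xc.T @ ye),
            W[1, 0] * (Xe.T @ yc) + W[1, 1] * (Xe.T @ ye),
        ]
    )
    cov = np.linalg.inv(XtX)
    beta = cov @ Xty
    rho = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
    return (
        float(beta[1]),
        float(np.sqrt(cov[1, 1])),
        float(beta[kc + 1]),
        float(np.sqrt(cov[kc + 1, kc + 1])),
        float(rho),
    )


def fit_sure(df: pd.DataFrame, spec: RegressionSpec) -> IncrementalEstimate:
    """Fit the cost/effect SUR system on a completed analysis table.

    ``df`` is one row per participant with a 0/1 ``arm01`` treatment
    indicator.  Returns the treatment coefficients of both equations with
    their FGLS standard errors and the residual correlation.
    """
    Xc, yc, names_c = _design(df, spec.cost_outcome, spec.cost_covariates)
    Xe, ye, names_e = _design(df, spec.effect_outcome, spec.effect_covariates)
    _check_rank(Xc, names_c, "cost")
    _check_rank(Xe, names_e, "effect")
    if np.var(ye) == 0:
        raise DegenerateFitError(
            f"effect outcome {spec.effect_outcome!r} has zero variance"
        )
    dc, se_c, de, se_e, rho = _fit_sur_arrays(Xc, yc, Xe, ye)
    n = len(df)
    return IncrementalEstimate(
        delta_cost=dc,
        se_cost=se_c,
        delta_effect=de,
        se_effect=se_e,
        residual_correlation=rho,
        n=n,
        df=n - Xe.shape[1],
    )


def adjusted_difference(
    df: pd.DataFrame, outcome: str, baseline_covariates=()
) -> tuple[float, float]:
    """Baseline-adjusted between-arm difference for a single outcome.

    Ordinary least squares of the outcome on the treatment indicator plus
    the named baseline covariates; returns (estimate, SE) of the treatment
    coefficient.  With no covariates and a binary outcome this is exactly
    the raw responder-rate difference.
    """
    X, y, names = _design(df, outcome, baseline_covariates)
    _check_rank(X, names, outcome)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])
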