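"""End-to-end evaluation: costing -> outcomes -> imputation -> SUR ->
bootstrap -> ICER / CE plane / CEAC -> sensitivity, with a reproducible
result bundle (CSV tables, JSON manifest, optional figures).

Every number in the bundle is re-derivable from the emitted CSVs; figures
are drawn from the same tables.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict, is_dataclass

import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    DEFAULT_SCENARIOS,
    DEFAULT_WTP_GRID,
    BootstrapDistribution,
    bootstrap_cea,
    ceac,
    icer,
    quadrants,
    run_sensitivity,
    wtp_at_certainty,
)
from .costing import UnitCostTable, societal_costs
from .dataset import PERIODS, TrialDataset, read_trial_csv
from .errors import ParameterError, UnattainedCertaintyError, UndefinedICERError
from .estimation import RegressionSpec, fit_sure
from .imputation import ImputationSpec, impute, pool
from .outcomes import OUTCOME_SPECS, UtilityMapping, classify_response, qaly_per_patient
from .synthetic import TrialConfig, apply_missingness, generate_trial

ESM_OUTCOMES = ("time_with_others", "momentary_anxiety", "momentary_paranoia")
ANALYSIS_OUTCOMES = ESM_OUTCOMES + ("qaly",)

_PERIOD_PREFIX = {"baseline": "bl", "post": "post", "followup": "fu"}


def regression_spec_for(outcome: str) -> RegressionSpec:
    """The study's per-outcome model: societal cost equation unadjusted;
    the effect equation adjusted by the baseline value only for
    time-with-others (which was imbalanced at baseline despite
    randomization)."""
    if outcome == "qaly":
        return RegressionSpec("cum_total", "qaly")
    if outcome not in ESM_OUTCOMES:
        raise ParameterError(f"unknown analysis outcome {outcome!r}")
    effect_covs = ("bl_time_with_others",) if outcome == "time_with_others" else ()
    return RegressionSpec("cum_total", f"resp_{outcome}", effect_covariates=effect_covs)


def control_baseline_sd(dataset: TrialDataset, column: str = "gpts") -> float:
    base = dataset.df[(dataset.df["period"] == "baseline") & (dataset.df["arm"] == "TAU")]
    return float(base[column].std(ddof=1))


def build_analysis_table(
    dataset: TrialDataset,
    prices: UnitCostTable,
    sd_ctrl_baseline: float | None = None,
    mapping: UtilityMapping = UtilityMapping(),
) -> pd.DataFrame:
    """One row per participant: covariates, per-period costs, cumulative
    costs, baseline/follow-up outcomes, responder flags, and the
    participant-level QALY contribution.

    Requires a completed (imputed or complete) dataset.  The GPTS
    standardization SD defaults to the control-arm baseline SD of this
    dataset but should be passed in fixed when the table is rebuilt per
    imputation or per bootstrap resample.
    """
    if sd_ctrl_baseline is None:
        sd_ctrl_baseline = control_baseline_sd(dataset)
    df = dataset.df
    base = df[df["period"] == "baseline"].set_index("id")
    out = pd.DataFrame(index=base.index)
    out["arm01"] = (base["arm"] == "VR-CBT").astype(float)
    out["male"] = (base["gender"] == "male").astype(float)
    for col in ("age", "non_dutch", "education", "safety_behavior", "paid_work"):
        out[col] = base[col].astype(float)

    for name in OUTCOME_SPECS:
        wide = df.pivot(index="id", columns="period", values=name)
        for period in PERIODS:
            out[f"{_PERIOD_PREFIX[period]}_{name}"] = wide[period]

    hosp_price = prices.price_per_service_unit.get("hospital_day", 0.0)
    out["bl_admission_cost"] = (
        base["hospital_days"].astype(float) * hosp_price * prices.cpi_factor
    )

    comp = {f"{p}_{c}": [] for p in _PERIOD_PREFIX.values() for c in
            ("health", "travel", "productivity", "total")}
    order = []
    for participant in dataset.participants():
        order.append(participant.id)
        costs = societal_costs(participant, prices)
        for period, prefix in _PERIOD_PREFIX.items():
            b = costs[period]
            comp[f"{prefix}_health"].append(b.health_care)
            comp[f"{prefix}_travel"].append(b.travel)
            comp[f"{prefix}_productivity"].append(b.productivity)
            comp[f"{prefix}_total"].append(b.total_societal)
    costs_df = pd.DataFrame(comp, index=order)
    out = out.join(costs_df)
    out["cum_health"] = out["post_health"] + out["fu_health"]
    out["cum_total"] = out["post_total"] + out["fu_total"]

    for name in ESM_OUTCOMES:
        spec = OUTCOME_SPECS[name]
        out[f"resp_{name}"] = [
            float(classify_response(b, f, spec))
            for b, f in zip(out[f"bl_{name}"], out[f"fu_{name}"])
        ]
    out["qaly"] = qaly_per_patient(
        out["bl_gpts"].to_numpy(), out["fu_gpts"].to_numpy(), sd_ctrl_baseline, mapping
    )
    return out.reset_index(names="id")


def summarize_by_period(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-participant costs and outcomes by period and arm
    (means pooled across imputations), in the layout of the study's
    costs-and-outcomes table."""
    stacked = pd.concat(tables, ignore_index=True)
    rows = []
    for arm01, arm in ((1.0, "VR-CBT"), (0.0, "TAU")):
        sub = stacked[stacked["arm01"] == arm01]
        for period, prefix in _PERIOD_PREFIX.items():
            row = {"arm": arm, "period": period}
            for comp in ("health", "travel", "productivity", "total"):
                col = sub[f"{prefix}_{comp}"]
                row[f"{comp}_mean"] = col.mean()
                row[f"{comp}_sd"] = col.std(ddof=1)
            for name in OUTCOME_SPECS:
                col = sub[f"{prefix}_{name}"]
                row[f"{name}_mean"] = col.mean()
                row[f"{name}_sd"] = col.std(ddof=1)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything one evaluation run needs.

    ``trial`` is either a :class:`TrialConfig` (simulate) or a path to a
    long-format trial CSV; ``unit_costs`` a :class:`UnitCostTable` or a
    YAML path (defaults when None).  ``bootstrap_mode`` is ``nested``
    (B/m bootstrap draws within each imputation, pooled by concatenation)
    or ``stacked`` (bootstrap once on the cell-wise average of the
    completed datasets).
    """

    trial: object = field(default_factory=TrialConfig)
    unit_costs: object = None
    outcomes: tuple = ANALYSIS_OUTCOMES
    m: int = 100
    B: int = 5000
    seed: int = 0
    bootstrap_mode: str = "nested"
    scenarios: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIOS))
    wtp_grid: tuple = DEFAULT_WTP_GRID
    certainty_level: float = 0.8
    outdir: str | None = None
    make_plots: bool = False


@dataclass
class ResultBundle:
    tables: dict
    distributions: dict
    manifest: dict

    def write(self, outdir: str, make_plots: bool = False) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        if make_plots:
            for name, dist in self.distributions.items():
                plot_ce_plane(dist, os.path.join(outdir, f"ce_plane_{name}.png"))
                curve_table = self.tables[f"ceac_{name}"]
                plot_ceac(curve_table, os.path.join(outdir, f"ceac_{name}.png"))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _load_trial(config: RunConfig) -> TrialDataset:
    if isinstance(config.trial, TrialConfig):
        ds = generate_trial(config.trial)
        if config.trial.dropout_post or config.trial.dropout_followup:
            ds = apply_missingness(ds, config.trial)
        return ds
    return read_trial_csv(config.trial)


def _load_prices(config: RunConfig) -> UnitCostTable:
    if config.unit_costs is None:
        return UnitCostTable()
    if isinstance(config.unit_costs, UnitCostTable):
        return config.unit_costs
    return UnitCostTable.from_yaml(config.unit_costs)


def _stack_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cell-wise average of the completed analysis tables (ids aligned)."""
    if len(tables) == 1:
        return tables[0]
    avg = tables[0].copy()
    cols = [c for c in avg.columns if c != "id"]
    avg[cols] = np.mean([t[cols].to_numpy(dtype=float) for t in tables], axis=0)
    return avg


def run_evaluation(config: RunConfig) -> ResultBundle:
    """Run the full evaluation pipeline and return the result bundle.

    Deterministic for a fixed ``config.seed``: the same configuration
    yields identical tables and manifest across invocations.
    """
    dataset = _load_trial(config)
    prices = _load_prices(config)
    n_missing_cells = int(dataset.df["missing"].fillna(0).sum())

    sd_ctrl = control_baseline_sd(dataset)
    if n_missing_cells > 0:
        spec_imp = ImputationSpec(m=config.m, seed=config.seed)
        completed = impute(dataset, spec_imp)
    else:
        completed = [dataset]
    tables = [build_analysis_table(d, prices, sd_ctrl) for d in completed]
    stacked = _stack_tables(tables)
    m_eff = len(tables)

    estimates_rows = []
    quadrant_rows = []
    out_tables = {}
    distributions = {}
    wtp_levels = {}
    seed_root = np.random.default_rng([config.seed, 2**20]).integers(
        0, 2**31 - 1, size=(len(config.outcomes), max(m_eff, 1))
    )
    for i, outcome in enumerate(config.outcomes):
        spec = regression_spec_for(outcome)
        fits = [fit_sure(t, spec) for t in tables]
        est = pool(fits) if len(fits) > 1 else fits[0]
        try:
            point_icer = icer(est.delta_cost, est.delta_effect)
        except UndefinedICERError:
            point_icer = math.nan
        estimates_rows.append(
            {
                "outcome": outcome,
                "delta_cost": est.delta_cost,
                "se_cost": est.se_cost,
                "delta_effect": est.delta_effect,
                "se_effect": est.se_effect,
                "rho": est.residual_correlation,
                "n": est.n,
                "df": est.df,
                "icer": point_icer,
            }
        )

        if config.bootstrap_mode == "nested" and m_eff > 1:
            per_imp = math.ceil(config.B / m_eff)
            parts = [
                bootstrap_cea(t, spec, B=per_imp, seed=int(seed_root[i, j]),
                              outcome_name=outcome)
                for j, t in enumerate(tables)
            ]
            draws = np.concatenate([p.draws for p in parts])[: config.B]
            dist = BootstrapDistribution(draws=draws, seed=config.seed, outcome_name=outcome)
        elif config.bootstrap_mode in ("nested", "stacked"):
            dist = bootstrap_cea(
                stacked, spec, B=config.B, seed=int(seed_root[i, 0]), outcome_name=outcome
            )
        else:
            raise ParameterError(f"unknown bootstrap_mode {config.bootstrap_mode!r}")
        distributions[outcome] = dist

        quad = quadrants(dist)
        quadrant_rows.append(
            {"outcome": outcome, "ne": quad.ne, "se": quad.se, "nw": quad.nw, "sw": quad.sw}
        )
        curve = ceac(dist, config.wtp_grid)
        out_tables[f"ceac_{outcome}"] = curve.to_frame()
        out_tables[f"draws_{outcome}"] = dist.to_frame()
        try:
            wtp_levels[outcome] = wtp_at_certainty(curve, config.certainty_level)
        except UnattainedCertaintyError:
            wtp_levels[outcome] = None

    sens = pd.concat(
        [
            run_sensitivity(stacked, regression_spec_for(o), config.scenarios, outcome_name=o)
            for o in config.outcomes
        ],
        ignore_index=True,
    )

    out_tables["summary"] = summarize_by_period(tables)
    out_tables["estimates"] = pd.DataFrame(estimates_rows)
    out_tables["quadrants"] = pd.DataFrame(quadrant_rows)
    out_tables["sensitivity"] = sens

    import pandas  # local to read versions without polluting module scope

    manifest = {
        "package": "trialcea",
        "version": __version__,
        "seed": config.seed,
        "B": config.B,
        "m": m_eff,
        "bootstrap_mode": config.bootstrap_mode,
        "n_participants": len(dataset),
        "n_missing_periods": n_missing_cells,
        "sd_ctrl_baseline_gpts": sd_ctrl,
        "certainty_level": config.certainty_level,
        "wtp_at_certainty": wtp_levels,
        "config_hash": _config_hash(config),
        "versions": {"numpy": np.__version__, "pandas": pandas.__version__},
    }
    bundle = ResultBundle(tables=out_tables, distributions=distributions, manifest=manifest)
    if config.outdir:
        bundle.write(config.outdir, make_plots=config.make_plots)
    return bundle


# ---------------------------------------------------------------------------
# figures (drawn from the emitted tables / distributions only)
# ---------------------------------------------------------------------------

def plot_ce_plane(dist: BootstrapDistribution, path: str) -> None:
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 5))
    ax = fig.subplots()
    ax.scatter(dist.delta_effect, dist.delta_cost, s=4, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel(f"incremental effect ({dist.outcome_name})")
    ax.set_ylabel("incremental societal cost (EUR)")
    ax.set_title("Cost-effectiveness plane")
    fig.savefig(path, dpi=120)


def plot_ceac(curve_table: pd.DataFrame, path: str) -> None:
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 4))
    ax = fig.subplots()
    ax.plot(curve_table["wtp"], curve_table["probability"])
    ax.set_ylim(0, 1)
    ax.set_xlabel("willingness-to-pay ceiling (EUR per effect unit)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.savefig(path, dpi=120)
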