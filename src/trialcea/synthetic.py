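"""Synthetic two-arm trial generator.

Emulates the statistical structure of a 6-month randomized trial of add-on
virtual-reality CBT versus treatment as usual in psychosis (two arms of
n=58 by default): right-skewed, admission-driven societal costs; a
paranoid-ideation score (GPTS) with scale floor 32; three 7-point-Likert /
proportion experience-sampling outcomes; and monotone dropout (8
participants lost at posttreatment, 12 more at follow-up).

Bounded outcomes (GPTS, Likert means, the time-with-others proportion) are
drawn from truncated normals whose *truncated* mean and SD equal the
configured targets — the underlying location/scale are solved numerically —
so arm-level sample means converge to the configured calibration values.

Admission days are a zero-truncated negative binomial realized as
1 + NB(mean-1, shape), which keeps the expectation closed-form for the
analytic cost helpers while preserving the heavy right tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .costing import UnitCostTable, DAYS_PER_DISPENSING_MONTH
import math

from .dataset import ARMS, PERIODS, RESOURCE_COLUMNS, OUTCOME_COLUMNS, TrialDataset
from .errors import ParameterError

ESM_OUTCOMES = ("time_with_others", "momentary_anxiety", "momentary_paranoia")

#: baseline calibration of outcome distributions: arm -> (mean, sd)
DEFAULT_GPTS_BASELINE = {"VR-CBT": (85.0, 34.0), "TAU": (77.0, 31.0)}
DEFAULT_ESM_BASELINE = {
    "time_with_others": {"VR-CBT": (0.416, 0.256), "TAU": (0.364, 0.266)},
    "momentary_anxiety": {"VR-CBT": (2.986, 1.120), "TAU": (3.259, 1.484)},
    "momentary_paranoia": {"VR-CBT": (3.064, 1.393), "TAU": (3.259, 1.418)},
}
OUTCOME_BOUNDS = {
    "gpts": (32.0, np.inf),
    "time_with_others": (0.0, 1.0),
    "momentary_anxiety": (1.0, 7.0),
    "momentary_paranoia": (1.0, 7.0),
}

#: probability of any psychiatric admission, per arm and period, calibrated
#: so expected per-capita admission days match the study's printed totals
#: (VR-CBT 233/101/0 days, TAU 138/20/68 days over n=58 per period) at a
#: mean stay of 25 days.
DEFAULT_ADMISSION_RATES = {
    ("VR-CBT", "baseline"): 233 / 58 / 25,
    ("VR-CBT", "post"): 101 / 58 / 25,
    ("VR-CBT", "followup"): 0.0,
    ("TAU", "baseline"): 138 / 58 / 25,
    ("TAU", "post"): 20 / 58 / 25,
    ("TAU", "followup"): 68 / 58 / 25,
}


@dataclass
class TrialConfig:
    """Study conditions for one synthetic trial.

    Treatment effects are parameterized on the scale the analysis uses:
    ``effect_gpts`` is the extra mean 6-month GPTS score reduction in the
    treated arm (score points), ``effect_response`` the difference in
    responder probability on each experience-sampling outcome.
    """

    n_per_arm: int = 58
    seed: int = 0

    # --- treatment effects ------------------------------------------------
    effect_gpts: float = 16.0
    gpts_change_ctrl: float = -2.0
    gpts_noise_sd: float = 15.0
    effect_response: float = 0.19
    response_rate_ctrl: float = 0.22
    improvement_sd: float = 0.25
    post_fraction: float = 0.8  # share of the 6-month change realized at 3 months

    # --- baseline outcome calibration (target moments of bounded laws) ----
    gpts_baseline: dict = field(default_factory=lambda: dict(DEFAULT_GPTS_BASELINE))
    esm_baseline: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ESM_BASELINE.items()}
    )

    # --- resource use / costs ----------------------------------------------
    cost_admission_rate: dict = field(
        default_factory=lambda: dict(DEFAULT_ADMISSION_RATES)
    )
    admission_days_dist: tuple = (25.0, 1.5)  # (mean days | any, NB shape)
    psychiatrist_rate: float = 2.0
    nurse_rate: float = 6.0
    psychologist_rate: float = 1.0
    p_antipsychotic: float = 0.95
    antipsychotic_daily_price: float = 2.0
    p_antidepressant: float = 0.27
    antidepressant_daily_price: float = 0.60
    rx_days: int = 90
    vr_sessions: int = 16

    # --- productivity --------------------------------------------------------
    paid_work_rate: float = 0.112
    contract_hours: tuple = (28.0, 8.0, 8.0, 40.0)  # mean, sd, lo, hi
    sick_days_rate: float = 8.0
    hours_reduction_prob: float = 0.1
    hours_reduction: float = 8.0

    # --- demographics ---------------------------------------------------------
    p_male: float = 0.70
    age_dist: tuple = (38.0, 10.0, 18.0, 65.0)  # mean, sd, lo, hi
    p_non_dutch: float = 0.345
    education_probs: tuple = (0.28, 0.36, 0.16, 0.20)
    safety_baseline: dict = field(
        default_factory=lambda: {"VR-CBT": (28.8, 14.2), "TAU": (21.1, 16.0)}
    )

    # --- dropout ---------------------------------------------------------------
    dropout_post: int = 8
    dropout_followup: int = 12
    dropout_covariate: str | None = None  # MCAR when None

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ParameterError("n_per_arm must be >= 2")
        probs = {
            "effect_response + response_rate_ctrl": self.effect_response
            + self.response_rate_ctrl,
            "response_rate_ctrl": self.response_rate_ctrl,
            "p_antipsychotic": self.p_antipsychotic,
            "p_antidepressant": self.p_antidepressant,
            "paid_work_rate": self.paid_work_rate,
            "p_male": self.p_male,
            "p_non_dutch": self.p_non_dutch,
            "hours_reduction_prob": self.hours_reduction_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be a probability in [0, 1], got {p}")
        for key, rate in self.cost_admission_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"cost_admission_rate[{key}] must be in [0, 1]")
        if self.dropout_post < 0 or self.dropout_followup < 0:
            raise ParameterError("dropout counts must be >= 0")
        if self.dropout_post + self.dropout_followup > 2 * self.n_per_arm:
            raise ParameterError("dropout counts exceed total sample size")
        if not abs(sum(self.education_probs) - 1.0) < 1e-9:
            raise ParameterError("education_probs must sum to 1")
        mean_days, shape = self.admission_days_dist
        if mean_days < 1 or shape <= 0:
            raise ParameterError("admission_days_dist requires mean >= 1 and shape > 0")


def null_config(n_per_arm: int = 58, seed: int = 0, **overrides) -> TrialConfig:
    """A no-effect configuration with fully symmetric arms.

    Both arms share baseline distributions, admission rates, and outcome
    trajectories, and the treated arm attends no VR sessions, so every
    expected between-arm difference (costs and effects) is zero.
    """
    sym_gpts = {arm: DEFAULT_GPTS_BASELINE["TAU"] for arm in ARMS}
    sym_esm = {
        name: {arm: arms["TAU"] for arm in ARMS}
        for name, arms in DEFAULT_ESM_BASELINE.items()
    }
    sym_adm = {
        (arm, period): DEFAULT_ADMISSION_RATES[("TAU", period)]
        for arm in ARMS
        for period in PERIODS
    }
    sym_safety = {arm: (21.1, 16.0) for arm in ARMS}
    cfg = TrialConfig(
        n_per_arm=n_per_arm,
        seed=seed,
        effect_gpts=0.0,
        effect_response=0.0,
        gpts_baseline=sym_gpts,
        esm_baseline=sym_esm,
        cost_admission_rate=sym_adm,
        safety_baseline=sym_safety,
        vr_sessions=0,
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# truncated-normal moment inversion
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def truncated_normal_params(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """Location/scale of a truncated normal with given truncated moments.

    Solves for (mu, sigma) such that a normal(mu, sigma) truncated to
    [lower, upper] has the requested mean and SD.
    """
    if sd <= 0:
        raise ParameterError("sd must be > 0")

    def eqs(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        eqs, x0=[mean, np.log(sd)], full_output=True
    )
    if ier != 1:
        raise ParameterError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"on [{lower}, {upper}]: {msg}"
        )
    return float(sol[0]), float(np.exp(sol[1]))


def _sample_truncnorm(rng, mean, sd, lower, upper, size):
    mu, sigma = truncated_normal_params(mean, sd, lower, upper)
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _sample_admission_days(rng, mean_days, shape, size):
    """1 + NB(mean-1, shape): integer days >= 1, right-skewed."""
    extra_mean = mean_days - 1.0
    if extra_mean <= 0:
        return np.ones(size, dtype=int)
    p = shape / (shape + extra_mean)
    return 1 + rng.negative_binomial(shape, p, size=size)


def _improvement_mean(target_rate: float, threshold: float, sd: float) -> float:
    """Mean of the Normal(mu, sd) relative-improvement draw such that
    P(improvement >= threshold) equals the target responder rate."""
    target_rate = min(max(target_rate, 1e-6), 1 - 1e-6)
    return threshold - sd * stats.norm.ppf(1.0 - target_rate)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_trial(config: TrialConfig) -> TrialDataset:
    """Generate a complete (no-dropout) two-arm trial.

    Deterministic for a fixed ``config.seed``; apply
    :func:`apply_missingness` afterwards for the dropout pattern.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    resp_rates = {
        "VR-CBT": config.response_rate_ctrl + config.effect_response,
        "TAU": config.response_rate_ctrl,
    }
    for arm in ARMS:
        n = config.n_per_arm
        male = rng.random(n) < config.p_male
        age = _sample_truncnorm(rng, *config.age_dist[:2], *config.age_dist[2:], n)
        non_dutch = rng.random(n) < config.p_non_dutch
        education = rng.choice(4, size=n, p=config.education_probs)
        s_mean, s_sd = config.safety_baseline[arm]
        safety = _sample_truncnorm(rng, s_mean, s_sd, 0.0, np.inf, n)
        paid_work = rng.random(n) < config.paid_work_rate
        h_mean, h_sd, h_lo, h_hi = config.contract_hours
        hours_bl = np.where(
            paid_work, np.round(_sample_truncnorm(rng, h_mean, h_sd, h_lo, h_hi, n)), 0.0
        )

        # outcome trajectories -------------------------------------------------
        g_mean, g_sd = config.gpts_baseline[arm]
        g_lo, g_hi = OUTCOME_BOUNDS["gpts"]
        gpts_bl = _sample_truncnorm(rng, g_mean, g_sd, g_lo, g_hi, n)
        change_mean = config.gpts_change_ctrl - (
            config.effect_gpts if arm == "VR-CBT" else 0.0
        )
        gpts_change = change_mean + rng.normal(0.0, config.gpts_noise_sd, n)
        gpts = {
            "baseline": gpts_bl,
            "post": np.maximum(g_lo, gpts_bl + config.post_fraction * gpts_change),
            "followup": np.maximum(g_lo, gpts_bl + gpts_change),
        }

        mu_impr = _improvement_mean(resp_rates[arm], 0.20, config.improvement_sd)
        esm = {}
        for name in ESM_OUTCOMES:
            mean, sd = config.esm_baseline[name][arm]
            lo, hi = OUTCOME_BOUNDS[name]
            bl = _sample_truncnorm(rng, mean, sd, lo, hi, n)
            impr = rng.normal(mu_impr, config.improvement_sd, n)
            sign = 1.0 if name == "time_with_others" else -1.0
            esm[name] = {
                "baseline": bl,
                "post": np.clip(bl * (1.0 + sign * config.post_fraction * impr), lo, hi),
                "followup": np.clip(bl * (1.0 + sign * impr), lo, hi),
            }

        # resource use ---------------------------------------------------------
        rx_ap = rng.random(n) < config.p_antipsychotic
        rx_ad = rng.random(n) < config.p_antidepressant
        mean_days, shape = config.admission_days_dist
        for period in PERIODS:
            any_adm = rng.random(n) < config.cost_admission_rate[(arm, period)]
            days = np.where(
                any_adm, _sample_admission_days(rng, mean_days, shape, n), 0
            )
            psy = rng.poisson(config.psychiatrist_rate, n)
            nurse = rng.poisson(config.nurse_rate, n)
            psych = rng.poisson(config.psychologist_rate, n)
            vr = np.full(n, config.vr_sessions if (arm == "VR-CBT" and period == "post") else 0)
            visits = psy + nurse + psych + vr
            if period == "baseline":
                hours = hours_bl
                sick = np.where(paid_work, rng.poisson(config.sick_days_rate, n), 0)
            else:
                reduce = (rng.random(n) < config.hours_reduction_prob) & paid_work
                hours = np.where(
                    reduce, np.maximum(0.0, hours_bl - config.hours_reduction), hours_bl
                )
                sick = np.where(paid_work, rng.poisson(config.sick_days_rate, n), 0)
            for i in range(n):
                rows.append(
                    {
                        "id": pid + i,
                        "period": period,
                        "arm": arm,
                        "gender": "male" if male[i] else "female",
                        "age": round(float(age[i]), 1),
                        "non_dutch": int(non_dutch[i]),
                        "education": int(education[i]),
                        "safety_behavior": round(float(safety[i]), 1),
                        "paid_work": int(paid_work[i]),
                        "hospital_days": int(days[i]),
                        "psychiatrist_visits": int(psy[i]),
                        "nurse_visits": int(nurse[i]),
                        "psychologist_sessions": int(psych[i]),
                        "vr_sessions": int(vr[i]),
                        "rx_antipsychotic_price": config.antipsychotic_daily_price
                        if rx_ap[i]
                        else 0.0,
                        "rx_antipsychotic_days": config.rx_days if rx_ap[i] else 0,
                        "rx_antipsychotic_first": 0,
                        "rx_antidepressant_price": config.antidepressant_daily_price
                        if rx_ad[i]
                        else 0.0,
                        "rx_antidepressant_days": config.rx_days if rx_ad[i] else 0,
                        "rx_antidepressant_first": 0,
                        "health_visits": int(visits[i]),
                        "sick_leave_days": int(sick[i]),
                        "contract_hours_per_week": float(hours[i]),
                        "gpts": float(gpts[period][i]),
                        "time_with_others": float(esm["time_with_others"][period][i]),
                        "momentary_anxiety": float(esm["momentary_anxiety"][period][i]),
                        "momentary_paranoia": float(esm["momentary_paranoia"][period][i]),
                        "missing": 0,
                    }
                )
        pid += n
    df = pd.DataFrame(rows)
    order = pd.Categorical(df["period"], categories=PERIODS, ordered=True)
    df = df.assign(_order=order).sort_values(["id", "_order"]).drop(columns="_order")
    return TrialDataset(df.reset_index(drop=True))


def apply_missingness(dataset: TrialDataset, config: TrialConfig) -> TrialDataset:
    """Impose monotone dropout on a complete trial.

    Exactly ``dropout_post`` participants lose their posttreatment *and*
    follow-up assessments; ``dropout_followup`` additional participants
    lose the follow-up only, so missingness is monotone in time.  Dropout
    is completely at random by default; setting ``config.dropout_covariate``
    to a baseline column name makes selection probability increase with
    that covariate.
    """
    config.validate()
    if config.dropout_post == 0 and config.dropout_followup == 0:
        return dataset.copy()
    ds = dataset.copy()
    ids = ds.df.loc[ds.df["period"] == "baseline", "id"].to_numpy()
    n_total = len(ids)
    if config.dropout_post + config.dropout_followup > n_total:
        raise ParameterError("requested dropout exceeds sample size")
    rng = np.random.default_rng([config.seed, 104729])
    if config.dropout_covariate is not None:
        col = config.dropout_covariate
        base = ds.df[ds.df["period"] == "baseline"].set_index("id").loc[ids]
        z = base[col].to_numpy(dtype=float)
        z = (z - z.mean()) / (z.std() or 1.0)
        weights = np.exp(z)
        weights /= weights.sum()
    else:
        weights = None
    chosen = rng.choice(
        ids, size=config.dropout_post + config.dropout_followup, replace=False, p=weights
    )
    lost_post = set(chosen[: config.dropout_post].tolist())
    lost_fu = set(chosen.tolist())  # monotone: post-dropouts stay missing

    df = ds.df
    blank_cols = list(RESOURCE_COLUMNS + OUTCOME_COLUMNS)
    mask_post = df["id"].isin(lost_post) & (df["period"] == "post")
    mask_fu = df["id"].isin(lost_fu) & (df["period"] == "followup")
    for mask in (mask_post, mask_fu):
        df.loc[mask, blank_cols] = np.nan
        df.loc[mask, "missing"] = 1
    return TrialDataset(df, validate=False)


# ---------------------------------------------------------------------------
# analytic expectations (for calibration checks)
# ---------------------------------------------------------------------------

def expected_health_cost(
    config: TrialConfig, prices: UnitCostTable, arm: str, period: str
) -> float:
    """Expected per-capita direct medical cost implied by the configuration."""
    mean_days, _ = config.admission_days_dist
    c = config.cost_admission_rate[(arm, period)] * mean_days
    c *= prices.price_per_service_unit["hospital_day"]
    c += config.psychiatrist_rate * prices.price_per_service_unit["psychiatrist_visit"]
    c += config.nurse_rate * prices.price_per_service_unit["nurse_visit"]
    c += config.psychologist_rate * prices.price_per_service_unit["psychologist_session"]
    if arm == "VR-CBT" and period == "post":
        c += config.vr_sessions * prices.price_per_service_unit["vr_cbt_session"]
    months = math.ceil(config.rx_days / DAYS_PER_DISPENSING_MONTH)
    c += config.p_antipsychotic * (
        config.antipsychotic_daily_price * config.rx_days
        + prices.dispensing_monthly * months
    )
    c += config.p_antidepressant * (
        config.antidepressant_daily_price * config.rx_days
        + prices.dispensing_monthly * months
    )
    if arm == "VR-CBT" and period == "post" and config.vr_sessions > 0:
        c += prices.vr_per_patient_course
    return c * prices.cpi_factor


def expected_travel_cost(
    config: TrialConfig, prices: UnitCostTable, arm: str, period: str
) -> float:
    """Expected per-capita travel cost implied by the configuration."""
    visits = config.psychiatrist_rate + config.nurse_rate + config.psychologist_rate
    if arm == "VR-CBT" and period == "post":
        visits += config.vr_sessions
    return visits * 2.0 * prices.travel_km * prices.cost_per_km * prices.cpi_factor
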