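"""Bootstrap CEA: ICER, quadrants, CEAC, willingness-to-pay, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from trialcea import (
    BootstrapDistribution,
    ParameterError,
    UnattainedCertaintyError,
    UndefinedICERError,
    bootstrap_cea,
    ceac,
    icer,
    incremental,
    quadrants,
    run_sensitivity,
    wtp_at_certainty,
)
from trialcea.cea import CeacCurve

from test_estimation import SPEC, _simulate_table


def _dist(dc, de, seed=0):
    return BootstrapDistribution(
        draws=np.column_stack([np.asarray(dc, float), np.asarray(de, float)]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dc, de, expected",
    [
        (2343.0, 0.12, 19525.0),   # cost per extra momentary-anxiety responder
        (2343.0, 0.29, 2343.0 / 0.29),
        (0.0, 0.5, 0.0),
        (-100.0, 0.1, -1000.0),    # dominant: cheaper and better
    ],
)
def test_icer_examples(dc, de, expected):
    assert icer(dc, de) == pytest.approx(expected)


def test_icer_zero_effect_undefined():
    with pytest.raises(UndefinedICERError):
        icer(100.0, 0.0)


def test_incremental_is_plain_difference():
    assert incremental(3917.0, 1686.0) == pytest.approx(2231.0)
    assert incremental(4393.0, 2050.0) == pytest.approx(2343.0)


# ---------------------------------------------------------------------------
# quadrants
# ---------------------------------------------------------------------------

def test_quadrant_classification():
    d = _dist([10, 10, -10, -10], [1, -1, 1, -1])
    q = quadrants(d)
    assert (q.ne, q.nw, q.se, q.sw) == (0.25, 0.25, 0.25, 0.25)


def test_quadrant_boundary_ties_go_north_east():
    q = quadrants(_dist([0.0], [0.0]))
    assert q.ne == 1.0


def test_quadrants_sum_to_one(rng):
    d = _dist(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
    q = quadrants(d)
    assert q.ne + q.nw + q.se + q.sw == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------

def test_ceac_single_draw_steps_at_the_icer():
    """One draw at (2343, 0.048): cost-effective exactly when
    lambda * 0.048 > 2343, i.e. above EUR 48,812.50."""
    d = _dist([2343.0], [0.048])
    grid = [0, 48_500, 49_000, 100_000]
    curve = ceac(d, grid)
    assert list(curve.probability) == [0.0, 0.0, 1.0, 1.0]


def test_ceac_at_zero_wtp_is_probability_of_saving_money(rng):
    dc = rng.normal(100, 300, 400)
    d = _dist(dc, rng.normal(0.05, 0.02, 400))
    curve = ceac(d, [0])
    assert curve.probability[0] == pytest.approx(np.mean(-dc > 0))


def test_ceac_limit_equals_effect_positive_mass(rng):
    """At very high ceilings the curve approaches P(delta_effect > 0)."""
    de = rng.normal(0.05, 0.05, 500)
    d = _dist(rng.normal(2000, 500, 500), de)
    curve = ceac(d, [10**9])
    assert curve.probability[0] == pytest.approx(np.mean(de > 0))


def test_ceac_matches_brute_force_nmb_oracle(rng):
    draws_c = rng.normal(2000, 800, 200)
    draws_e = rng.normal(0.05, 0.04, 200)
    d = _dist(draws_c, draws_e)
    grid = list(range(0, 100_001, 10_000))
    curve = ceac(d, grid)
    for lam, p in zip(curve.wtp_grid, curve.probability):
        oracle = sum(1 for c, e in zip(draws_c, draws_e) if lam * e - c > 0) / 200
        assert p == pytest.approx(oracle)


def test_ceac_monotone_when_effects_nonnegative(rng):
    d = _dist(rng.normal(2000, 800, 300), rng.uniform(0.0, 0.1, 300))
    curve = ceac(d)
    assert (np.diff(curve.probability) >= -1e-12).all()


def test_ceac_rejects_bad_grid(rng):
    d = _dist([1.0], [1.0])
    with pytest.raises(ParameterError):
        ceac(d, [])
    with pytest.raises(ParameterError):
        ceac(d, [0, 0, 100])


# ---------------------------------------------------------------------------
# willingness-to-pay at a certainty level
# ---------------------------------------------------------------------------

def test_wtp_at_certainty_first_crossing():
    curve = CeacCurve(
        wtp_grid=np.array([0.0, 500.0, 1000.0, 1500.0]),
        probability=np.array([0.1, 0.5, 0.8, 0.9]),
    )
    assert wtp_at_certainty(curve, 0.8) == 1000.0
    assert wtp_at_certainty(curve, 0.05) == 0.0


def test_wtp_at_certainty_unattained():
    curve = CeacCurve(np.array([0.0, 100.0]), np.array([0.1, 0.2]))
    with pytest.raises(UnattainedCertaintyError):
        wtp_at_certainty(curve, 0.8)
    with pytest.raises(ParameterError):
        wtp_at_certainty(curve, 1.5)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_reproducible_and_shaped(rng):
    df = _simulate_table(120, rng)
    a = bootstrap_cea(df, SPEC, B=50, seed=9)
    b = bootstrap_cea(df, SPEC, B=50, seed=9)
    np.testing.assert_array_equal(a.draws, b.draws)
    assert a.draws.shape == (50, 2)
    c = bootstrap_cea(df, SPEC, B=50, seed=10)
    assert not np.array_equal(a.draws, c.draws)


def test_bootstrap_mean_tracks_point_estimate(rng):
    """The bootstrap means of delta-cost/delta-effect lie within ~2 Monte
    Carlo standard errors of the full-sample SUR estimates."""
    from trialcea import fit_sure

    df = _simulate_table(400, rng)
    est = fit_sure(df, SPEC)
    d = bootstrap_cea(df, SPEC, B=400, seed=4)
    for mean, draws_col, point in (
        ("cost", d.delta_cost, est.delta_cost),
        ("effect", d.delta_effect, est.delta_effect),
    ):
        mc_se = draws_col.std(ddof=1) / np.sqrt(d.B)
        assert abs(draws_col.mean() - point) < 4 * mc_se + 1e-12


def test_bootstrap_requires_both_arms(rng):
    df = _simulate_table(40, rng)
    with pytest.raises(ParameterError):
        bootstrap_cea(df[df["arm01"] == 1.0], SPEC, B=10, seed=0)
    with pytest.raises(ParameterError):
        bootstrap_cea(df, SPEC, B=0, seed=0)


# ---------------------------------------------------------------------------
# sensitivity scenarios
# ---------------------------------------------------------------------------

def test_sensitivity_none_scenario_reproduces_main_fit(rng):
    from trialcea import fit_sure

    df = _simulate_table(200, rng)
    table = run_sensitivity(df, SPEC, scenarios={"none": ()})
    est = fit_sure(df, SPEC)
    row = table.iloc[0]
    assert row["delta_cost"] == est.delta_cost
    assert row["delta_effect"] == est.delta_effect
    assert row["icer"] == pytest.approx(est.delta_cost / est.delta_effect)


def test_sensitivity_adjusting_for_confounder_moves_estimate(rng):
    """A covariate imbalanced across arms biases the crude difference;
    adjusting for it recovers the truth."""
    n = 4000
    arm = np.repeat([0.0, 1.0], n // 2)
    z = rng.normal(0, 1, n) + 1.0 * arm  # imbalanced baseline covariate
    df = pd.DataFrame(
        {
            "arm01": arm,
            "z": z,
            "cost": 1000.0 + 0.0 * arm + 800.0 * z + rng.normal(0, 300, n),
            "effect": 0.1 + 0.05 * arm + rng.normal(0, 0.05, n),
        }
    )
    table = run_sensitivity(df, SPEC, scenarios={"crude": (), "adjusted": ("z",)})
    crude = table.set_index("scenario").loc["crude", "delta_cost"]
    adjusted = table.set_index("scenario").loc["adjusted", "delta_cost"]
    assert abs(crude - 800.0) < 100.0  # crude absorbs the confounding
    assert abs(adjusted - 0.0) < 60.0


def test_sensitivity_orthogonal_scenario_stays_close(rng):
    df = _simulate_table(3000, rng, with_covariate=True)
    table = run_sensitivity(df, SPEC, scenarios={"none": (), "extra": ("z",)})
    pivot = table.set_index("scenario")
    assert pivot.loc["extra", "delta_cost"] == pytest.approx(
        pivot.loc["none", "delta_cost"], rel=0.1
    )
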