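"""Hill (allosteric sigmoidal) curve: evaluation, solving, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from katharoseq import (
    HillCurveModel,
    HillFit,
    SimulationParams,
    composition_points,
    fit_hill,
    generate_titration,
    hill_curve,
    invert_hill,
    r_squared,
    solve_two_point,
)
from katharoseq.errors import DegenerateFitError, InsufficientPointsError

params_st = st.tuples(
    st.floats(0.3, 1.0),  # ymax
    st.floats(1.0, 1e4),  # k_half
    st.floats(0.2, 5.0),  # h
)


def test_half_saturation_identity():
    assert hill_curve(96.88, 1.0, 96.88, 1.377) == pytest.approx(0.5)


def test_zero_dose_gives_zero():
    assert hill_curve(0.0, 0.9, 100.0, 2.0) == 0.0


def test_curve_value_near_printed_composition_at_500_cells():
    # direct arithmetic: (500/96.88)^1.3685 / (1 + ...) = 0.90430
    assert hill_curve(500, 1.0, 96.88, 1.3685) == pytest.approx(0.90430, abs=5e-5)


def test_negative_dose_rejected():
    with pytest.raises(ValueError):
        hill_curve(-1.0, 1.0, 10.0, 1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(params=params_st, xs=st.lists(st.floats(0.01, 1e5), min_size=2, max_size=6))
def test_strictly_increasing_in_dose(params, xs):
    ymax, k, h = params
    xs = np.sort(np.unique(xs))
    # strictness is asserted between doses separated beyond float noise
    xs = xs[np.concatenate([[True], np.diff(xs) / xs[1:] > 1e-9])]
    ys = hill_curve(xs, ymax, k, h)
    assert np.all(np.diff(ys) >= 0)
    # strictly increasing wherever the curve is not float-saturated
    unsaturated = ys[:-1] < ymax * (1 - 1e-9)
    assert np.all(np.diff(ys)[unsaturated] > 0)


def test_two_point_solver_reconstructs_background_load():
    """The two printed mean compositions pin down K within ~0.5% of 96.88."""
    k, h = solve_two_point(50, 0.288, 500, 0.906, ymax=1.0)
    assert k == pytest.approx(96.88, rel=0.01)
    assert h == pytest.approx(1.377, abs=0.01)
    # the curve passes exactly through both points
    assert hill_curve(50, 1.0, k, h) == pytest.approx(0.288, abs=1e-12)
    assert hill_curve(500, 1.0, k, h) == pytest.approx(0.906, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(params=params_st, x1=st.floats(0.1, 100.0), ratio=st.floats(1.5, 100.0))
def test_two_point_solver_exact_recovery(params, x1, ratio):
    ymax, k, h = params
    x2 = x1 * ratio
    y1, y2 = hill_curve(x1, ymax, k, h), hill_curve(x2, ymax, k, h)
    if not (1e-9 < y1 < y2 < ymax - 1e-9):
        return
    k_est, h_est = solve_two_point(x1, y1, x2, y2, ymax)
    assert k_est == pytest.approx(k, rel=1e-6)
    assert h_est == pytest.approx(h, rel=1e-6)


def test_two_point_solver_degenerate_inputs():
    with pytest.raises(DegenerateFitError):
        solve_two_point(50, 0.5, 500, 0.5, 1.0)  # y1 == y2
    with pytest.raises(DegenerateFitError):
        solve_two_point(500, 0.2, 50, 0.8, 1.0)  # x1 > x2
    with pytest.raises(DegenerateFitError):
        solve_two_point(50, 0.8, 500, 0.2, 1.0)  # non-monotone


def test_noiseless_fit_recovers_parameters():
    truth = dict(ymax=0.95, k_half=100.0, h=1.4)
    x = np.array([5.0, 20.0, 50.0, 100.0, 200.0, 500.0, 2000.0, 5000.0])
    y = hill_curve(x, **truth)
    fit = fit_hill(list(zip(x, y)), ymax_mode="free")
    assert fit.converged
    assert fit.ymax == pytest.approx(truth["ymax"], rel=1e-6)
    assert fit.k_half == pytest.approx(truth["k_half"], rel=1e-6)
    assert fit.h == pytest.approx(truth["h"], rel=1e-6)


def test_fit_matches_grid_search_oracle():
    """SSres at the fitted optimum is within 1% of an exhaustive lattice."""
    rng = np.random.default_rng(42)
    x = np.repeat([5.0, 50.0, 500.0, 5000.0], 10)
    y = np.clip(
        hill_curve(x, 0.95, 100.0, 1.4) + rng.normal(0, 0.03, x.size), 0.0, 1.0
    )
    fit = fit_hill(list(zip(x, y)), ymax_mode="free")

    ymax_grid = np.linspace(0.85, 1.0, 16)
    k_grid = np.geomspace(20.0, 500.0, 100)
    h_grid = np.linspace(0.8, 2.2, 57)
    best = np.inf
    for ymax in ymax_grid:
        r = (x[None, :] / k_grid[:, None])
        for h in h_grid:
            rh = r**h
            pred = ymax * rh / (1.0 + rh)
            best = min(best, float(((pred - y[None, :]) ** 2).sum(axis=1).min()))
    ss_fit = float(((fit.predict(x) - y) ** 2).sum())
    assert ss_fit <= 1.01 * best


def test_fit_refused_without_response_variance():
    fit = fit_hill([(5, 0.4), (50, 0.4), (500, 0.4)], ymax_mode="free")
    assert not fit.converged
    assert np.isnan(fit.r_squared)


def test_insufficient_distinct_levels():
    with pytest.raises(InsufficientPointsError):
        fit_hill([(5, 0.1), (5, 0.2), (50, 0.6)], ymax_mode="free")
    with pytest.raises(InsufficientPointsError):
        fit_hill([(5, 0.1), (5, 0.2)], ymax_mode="fixed_1")


def test_two_level_fixed_fit_agrees_with_closed_form():
    """With two dose levels and Ymax fixed, the least-squares curve is the
    closed-form solution through the level means."""
    pts = [(50, 0.25), (50, 0.32), (500, 0.88), (500, 0.93)]
    fit = fit_hill(pts, ymax_mode="fixed_1")
    k, h = solve_two_point(50, 0.285, 500, 0.905, 1.0)
    assert fit.ymax == 1.0
    assert fit.k_half == pytest.approx(k, rel=1e-12)
    assert fit.h == pytest.approx(h, rel=1e-12)


def test_invert_round_trip_and_half_max():
    fit = HillFit(ymax=0.9, k_half=250.0, h=1.7, r_squared=1.0, n_points=4)
    assert invert_hill(fit, 0.45) == pytest.approx(250.0)
    for y in (0.05, 0.3, 0.6, 0.89):
        x = invert_hill(fit, y)
        assert fit.predict(x) == pytest.approx(y, rel=1e-9)
    with pytest.raises(DegenerateFitError):
        invert_hill(fit, 0.9)


def test_reads_fit_half_saturation_is_the_printed_crossing():
    """At Ymax=1, inverting at 50% composition returns K½ itself (683 reads)."""
    fit = HillFit(
        ymax=1.0, k_half=683.0, h=1.2, r_squared=0.9, n_points=10, x_variable="reads"
    )
    assert invert_hill(fit, 0.5) == pytest.approx(683.0, rel=1e-12)


def test_r_squared_hand_computation():
    pts = [(10, 0.1), (100, 0.5), (1000, 0.8), (5000, 0.95)]
    fit = HillFit(ymax=1.0, k_half=100.0, h=1.0, r_squared=0.0, n_points=4)
    y = np.array([p[1] for p in pts])
    pred = fit.predict(np.array([p[0] for p in pts]))
    expected = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert r_squared(pts, fit) == pytest.approx(expected, rel=1e-12)


def test_r_squared_perfect_fit_is_one():
    fit = HillFit(ymax=0.9, k_half=50.0, h=1.3, r_squared=1.0, n_points=3)
    pts = [(x, fit.predict(x)) for x in (10.0, 60.0, 400.0)]
    assert r_squared(pts, fit) == pytest.approx(1.0)


def test_r_squared_errors():
    fit = HillFit(ymax=1.0, k_half=10.0, h=1.0, r_squared=0.0, n_points=2)
    with pytest.raises(InsufficientPointsError):
        r_squared([(1, 0.1)], fit)
    with pytest.raises(DegenerateFitError):
        r_squared([(1, 0.5), (2, 0.5)], fit)


def test_sklearn_estimator_protocol():
    model = HillCurveModel(ymax_mode="fixed_1", x_variable="reads")
    assert clone(model).get_params() == model.get_params()
    x = np.array([[50.0], [100.0], [500.0], [2000.0]])
    y = hill_curve(x[:, 0], 1.0, 300.0, 1.3)
    model.fit(x, y)
    assert model.k_half_ == pytest.approx(300.0, rel=1e-5)
    assert model.predict(x) == pytest.approx(y, rel=1e-5)
    assert model.score(x, y) == pytest.approx(1.0)


def _median_k_error(replicates: int, n_seeds: int = 8) -> float:
    params = SimulationParams(replicates_per_level=replicates, n_negatives=4)
    errors = []
    for seed in range(n_seeds):
        table, design = generate_titration(params, seed=1000 + seed)
        points, _ = composition_points(table, design, {"extraction_positive"})
        fit = fit_hill(
            [(p.input_cells, p.target_fraction) for p in points], ymax_mode="free"
        )
        errors.append(abs(fit.k_half - params.true_k_half) / params.true_k_half)
    return float(np.median(errors))


def test_k_half_error_shrinks_with_replication():
    errs = {n: _median_k_error(n) for n in (6, 18, 54)}
    assert errs[54] <= errs[6]
    assert errs[54] <= errs[18] * 1.5  # allow noise, forbid regression
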