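"""Boltzmann threshold evaluation, constrained fitting and comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myodti.synthetic_data import generate_fit_points
from myodti.threshold_model import (
    CELL_DEATH_THRESHOLD,
    NO_DAMAGE_THRESHOLD,
    REFERENCE_IN_VIVO_CELL_DEATH,
    DegenerateDesignError,
    FitConstraints,
    ThresholdModel,
    UnderdeterminedFitError,
    compare_thresholds,
    evaluate_threshold,
    fit_threshold,
    load_models,
    save_models,
    sse,
)

model_strategy = st.builds(
    ThresholdModel,
    K=st.floats(1.0, 40.0),
    alpha=st.floats(0.05, 3.0),
    t0=st.floats(30.0, 120.0),
    C=st.floats(0.0, 15.0),
)


class TestEvaluate:
    def test_midrange_value(self):
        # at t0 the sigmoid sits exactly at K/2 + C
        assert evaluate_threshold(CELL_DEATH_THRESHOLD, 90.0) == pytest.approx(13.6)

    def test_asymptotes(self):
        assert evaluate_threshold(CELL_DEATH_THRESHOLD, 1e9) == pytest.approx(5.5)
        assert evaluate_threshold(CELL_DEATH_THRESHOLD, -1e9) == pytest.approx(21.7)

    @given(model=model_strategy)
    @settings(max_examples=50, deadline=None)
    def test_midrange_identity(self, model):
        assert evaluate_threshold(model, model.t0) == pytest.approx(model.K / 2 + model.C)

    @given(model=model_strategy)
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_and_within_range(self, model):
        # stay where the exponential has not saturated in double precision
        t = np.linspace(model.t0 - 20 / model.alpha, model.t0 + 20 / model.alpha, 60)
        v = evaluate_threshold(model, t)
        assert np.all(np.diff(v) < 0)
        assert np.all(v > model.C) and np.all(v < model.K + model.C)

    def test_increasing_in_K_and_C(self):
        base = evaluate_threshold(CELL_DEATH_THRESHOLD, 60.0)
        bigger_k = ThresholdModel(K=20.0, alpha=0.5, t0=90.0, C=5.5)
        bigger_c = ThresholdModel(K=16.2, alpha=0.5, t0=90.0, C=7.0)
        assert evaluate_threshold(bigger_k, 60.0) > base
        assert evaluate_threshold(bigger_c, 60.0) > base

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ThresholdModel(K=-1.0, alpha=0.5, t0=90.0, C=5.5)
        with pytest.raises(ValueError):
            ThresholdModel(K=16.2, alpha=0.5, t0=90.0, C=5.5, category="bogus")


class TestSse:
    def test_exact_curve_is_zero(self):
        pts = generate_fit_points(CELL_DEATH_THRESHOLD, np.arange(30, 121, 10.0), 0.0)
        assert sse(CELL_DEATH_THRESHOLD, pts) == pytest.approx(0.0, abs=1e-20)

    def test_known_offsets(self):
        t = np.array([40.0, 80.0])
        on_curve = evaluate_threshold(CELL_DEATH_THRESHOLD, t)
        one_off = [(40.0, on_curve[0] + 1.0)]
        assert sse(CELL_DEATH_THRESHOLD, one_off) == pytest.approx(1.0)
        two_off = [(40.0, on_curve[0] + 1.0), (80.0, on_curve[1] - 2.0)]
        assert sse(CELL_DEATH_THRESHOLD, two_off) == pytest.approx(5.0)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            sse(CELL_DEATH_THRESHOLD, [])


class TestCompare:
    def test_ex_vivo_versus_in_vivo_reference(self):
        # this study's cell-death curve sits 6.8 kPa (K) / 3.1 kPa (C) below
        # the in vivo reference
        deltas = compare_thresholds(CELL_DEATH_THRESHOLD, REFERENCE_IN_VIVO_CELL_DEATH)
        assert deltas["b_minus_a"]["K"] == pytest.approx(6.8)
        assert deltas["b_minus_a"]["C"] == pytest.approx(3.1)
        assert deltas["a_minus_b"]["K"] == pytest.approx(-6.8)

    def test_identical_models_zero_delta(self):
        deltas = compare_thresholds(CELL_DEATH_THRESHOLD, CELL_DEATH_THRESHOLD)
        assert all(v == 0.0 for v in deltas["b_minus_a"].values())

    def test_arbitrary_pair_hand_computed(self):
        a = ThresholdModel(K=10.0, alpha=0.2, t0=60.0, C=2.0)
        b = ThresholdModel(K=12.5, alpha=0.1, t0=80.0, C=3.0)
        d = compare_thresholds(a, b)["b_minus_a"]
        assert d == {"K": 2.5, "alpha": pytest.approx(-0.1), "t0": 20.0, "C": 1.0}


class TestFit:
    def test_noiseless_self_consistency(self):
        pts = generate_fit_points(CELL_DEATH_THRESHOLD, np.arange(30, 121, 5.0), 0.0)
        fit = fit_threshold(pts, category="cell_death", seed=0)
        assert np.allclose(fit.params, CELL_DEATH_THRESHOLD.params, atol=1e-4)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_recovery_of_random_truths(self):
        # multi-start bounded least squares recovers any in-bounds truth
        rng = np.random.default_rng(7)
        t_grid = np.arange(30, 121, 3.0)
        for i in range(20):
            truth = ThresholdModel(
                K=rng.uniform(3, 30), alpha=rng.uniform(0.08, 1.5),
                t0=rng.uniform(45, 105), C=rng.uniform(0.5, 15),
            )
            pts = generate_fit_points(truth, t_grid, 0.0, 1, seed=i)
            fit = fit_threshold(pts, category="reference", seed=i)
            assert np.allclose(fit.params, truth.params, atol=1e-4), (i, truth)

    def test_noisy_recovery_within_ten_percent(self):
        pts = generate_fit_points(
            CELL_DEATH_THRESHOLD, np.arange(30, 121, 15.0), 0.3, 5, seed=42
        )
        fit = fit_threshold(pts, category="cell_death", seed=42)
        assert abs(fit.K - 16.2) / 16.2 < 0.10

    def test_monte_carlo_median_error(self):
        # median relative error of K and C stays below 5 % at 0.3 kPa noise
        t_grid = np.arange(30, 121, 15.0)
        errs_k, errs_c = [], []
        for seed in range(100):
            pts = generate_fit_points(CELL_DEATH_THRESHOLD, t_grid, 0.3, 5, seed=seed)
            fit = fit_threshold(pts, category="cell_death", starts=6, seed=seed)
            errs_k.append(abs(fit.K - 16.2) / 16.2)
            errs_c.append(abs(fit.C - 5.5) / 5.5)
        assert np.median(errs_k) <= 0.05
        assert np.median(errs_c) <= 0.05

    def test_constraint_activation_near_bounds(self):
        # cell-death C is capped below 6 even when the data pull above it
        truth_high_c = ThresholdModel(K=16.2, alpha=0.5, t0=90.0, C=6.5)
        pts = generate_fit_points(truth_high_c, np.arange(30, 121, 5.0), 0.0)
        fit = fit_threshold(pts, category="cell_death", seed=0)
        assert fit.C <= 6.0
        assert fit.C > 5.0
        # no-damage C is floored above 3.7
        truth_low_c = ThresholdModel(K=13.1, alpha=0.5, t0=90.0, C=3.0)
        pts = generate_fit_points(truth_low_c, np.arange(30, 121, 5.0), 0.0)
        fit = fit_threshold(pts, category="no_damage", seed=0)
        assert fit.C >= 3.7

    def test_returned_model_is_local_fixed_point(self):
        from scipy.optimize import least_squares

        from myodti.threshold_model import _boltzmann

        pts = generate_fit_points(CELL_DEATH_THRESHOLD, np.arange(30, 121, 15.0), 0.3,
                                  3, seed=5)
        first = fit_threshold(pts, category="cell_death", seed=5)
        assert sse(first, pts) == pytest.approx(first.sse, rel=1e-9, abs=1e-12)
        # restarting the bounded solver from the returned parameters does not
        # improve the objective
        t, s = np.asarray(pts)[:, 0], np.asarray(pts)[:, 1]
        lo, hi = [1e-6, 1e-6, 30.0, 0.0], [50.0, 5.0, 120.0, 6.0]
        res = least_squares(lambda x: _boltzmann(x, t) - s,
                            np.clip(first.params, lo, hi), bounds=(lo, hi))
        assert 2 * res.cost >= first.sse - 1e-8

    def test_fixed_slope_and_midrange_workflow(self):
        # reference-style fit: alpha and t0 imposed, only K and C estimated
        pts = generate_fit_points(CELL_DEATH_THRESHOLD, np.arange(30, 121, 10.0), 0.0)
        constraints = FitConstraints(
            bounds={"K": (1e-6, 50.0), "C": (0.0, 20.0)},
            fixed={"alpha": 0.5, "t0": 90.0},
        )
        fit = fit_threshold(pts, constraints, category="cell_death", seed=0)
        assert fit.K == pytest.approx(16.2, abs=1e-6)
        assert fit.C == pytest.approx(5.5, abs=1e-6)

    def test_underdetermined_and_degenerate_designs(self):
        pts3 = generate_fit_points(CELL_DEATH_THRESHOLD, [30.0, 60.0, 90.0], 0.0)
        with pytest.raises(UnderdeterminedFitError):
            fit_threshold(pts3, category="cell_death")
        same_t = [(60.0, 10.0), (60.0, 11.0), (60.0, 12.0), (60.0, 13.0)]
        with pytest.raises(DegenerateDesignError):
            fit_threshold(same_t, FitConstraints.for_category("reference", (30.0, 120.0)))


def test_model_json_roundtrip(tmp_path):
    models = {"cell_death": CELL_DEATH_THRESHOLD, "no_damage": NO_DAMAGE_THRESHOLD}
    path = tmp_path / "models.json"
    save_models(models, path)
    loaded = load_models(path)
    assert loaded["cell_death"].params == CELL_DEATH_THRESHOLD.params
    assert loaded["no_damage"].category == "no_damage"
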