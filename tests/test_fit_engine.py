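"""Fit-engine tests: objective, global search, uncertainties, model choice."""

import numpy as np
import pytest

from lipidxrr.fit_engine import (
    FitConfig,
    FitParameter,
    build_stack,
    compare_models,
    cost,
    fit_stack,
    parameter_uncertainty,
    stack_slot_values,
)
from lipidxrr.stack_model import BUFFER, SILICON, LayerStack, ReflectivityCurve, Slab
from lipidxrr.synthetic import NoiseModel, default_q_grid, make_preset, simulate_curve


def one_slab_stack(d=30.0, rho=0.45, sigma=3.0):
    return LayerStack(BUFFER, [Slab(d, rho, sigma)], SILICON, 3.0)


def quick_config(seed=0, gens=80):
    return FitConfig(seed=seed, max_generations=gens)


class TestCost:
    def test_perfect_model_costs_zero(self):
        q = default_q_grid(50)
        R = simulate_curve(one_slab_stack(), q).R
        curve = ReflectivityCurve(q, R)
        assert cost(curve, R, FitConfig()) == 0.0

    def test_tenfold_offset_costs_one_decade_squared(self):
        q = default_q_grid(50)
        R = simulate_curve(one_slab_stack(), q).R
        curve = ReflectivityCurve(q, R)
        assert cost(curve, 10 * R, FitConfig()) == pytest.approx(1.0, rel=1e-9)

    def test_chi2_cost_is_quadratic_in_residuals(self):
        q = default_q_grid(50)
        R = simulate_curve(one_slab_stack(), q).R
        config = FitConfig(cost="chi2_weighted")
        curve1 = ReflectivityCurve(q, R * 1.01, dR=0.02 * R)
        curve2 = ReflectivityCurve(q, R * 1.02, dR=0.02 * R)
        c1 = cost(curve1, R, config)
        c2 = cost(curve2, R, config)
        assert c2 == pytest.approx(4 * c1, rel=1e-2)

    def test_nonpositive_data_masked_with_warning(self):
        q = default_q_grid(50)
        R = simulate_curve(one_slab_stack(), q).R
        R_bad = R.copy()
        R_bad[10] = 0.0
        curve = ReflectivityCurve(q, R_bad)
        with pytest.warns(UserWarning, match="masking"):
            assert cost(curve, R, FitConfig()) == 0.0


class TestFitStack:
    def test_single_parameter_matches_grid_search(self):
        truth = one_slab_stack(d=32.0)
        q = default_q_grid(100)
        curve = simulate_curve(truth, q)  # noiseless
        template = one_slab_stack(d=25.0)
        params = [
            FitParameter("slab0_d", 25.0, (20.0, 45.0)),
            FitParameter("background", 0.0, fixed=True),
        ]
        config = quick_config()
        result = fit_stack(curve, template, params, config)

        # independent brute-force oracle over the same bounds
        grid = np.arange(20.0, 45.0, 0.01)
        costs = []
        for d in grid:
            stack = build_stack(template, {"slab0_d": d})
            costs.append(cost(curve, simulate_curve(stack, q).R, config))
        d_grid = grid[int(np.argmin(costs))]
        assert result.values["slab0_d"] == pytest.approx(d_grid, abs=0.01)
        assert result.values["slab0_d"] == pytest.approx(32.0, abs=0.01)

    def test_deterministic_for_fixed_seed(self):
        truth = one_slab_stack()
        curve = simulate_curve(truth, default_q_grid(80), NoiseModel(seed=3))
        params = [
            FitParameter("slab0_d", 30.0, (20.0, 40.0)),
            FitParameter("slab0_rho", 0.45, (0.40, 0.50)),
        ]
        r1 = fit_stack(curve, truth, params, quick_config(seed=9))
        r2 = fit_stack(curve, truth, params, quick_config(seed=9))
        assert r1.values == r2.values
        assert r1.cost_value == r2.cost_value

    def test_bounds_and_fixed_values_respected(self):
        truth = one_slab_stack()
        curve = simulate_curve(truth, default_q_grid(60), NoiseModel(seed=1))
        template = one_slab_stack(rho=0.42)
        params = [
            FitParameter("slab0_d", 30.0, (25.0, 35.0)),
            FitParameter("slab0_rho", 0.42, fixed=True),
        ]
        result = fit_stack(curve, template, params, quick_config())
        assert 25.0 <= result.values["slab0_d"] <= 35.0
        assert result.values["slab0_rho"] == 0.42  # fixed never moves
        assert result.stack.slabs[0].electron_density == 0.42

    def test_no_free_parameters_is_an_error(self):
        curve = simulate_curve(one_slab_stack(), default_q_grid(30))
        params = [FitParameter("slab0_d", 30.0, fixed=True)]
        config = FitConfig(
            background=FitParameter("background", 0.0, fixed=True)
        )
        with pytest.raises(ValueError, match="no free parameters"):
            fit_stack(curve, one_slab_stack(), params, config)

    def test_unknown_slot_name_rejected(self):
        curve = simulate_curve(one_slab_stack(), default_q_grid(30))
        params = [FitParameter("slab7_d", 30.0, (20, 40))]
        with pytest.raises(ValueError, match="slab7_d"):
            fit_stack(curve, one_slab_stack(), params, quick_config())

    def test_best_so_far_cost_is_monotone(self):
        truth = one_slab_stack()
        curve = simulate_curve(truth, default_q_grid(60), NoiseModel(seed=2))
        params = [FitParameter("slab0_d", 30.0, (20.0, 40.0))]
        result = fit_stack(curve, truth, params, quick_config(seed=4))
        history = np.array(result.cost_history)
        assert np.all(np.diff(history) <= 0)
        assert result.cost_value <= history[0]

    def test_disrupted_film_converges_with_one_slab_template(self):
        # long-incubation disrupted film: a single diffuse slab suffices
        preset = make_preset("disrupted_one_slab")
        curve = simulate_curve(
            preset.stack, default_q_grid(150),
            NoiseModel("relative_gaussian", 0.02, seed=13),
        )
        params = [
            FitParameter("slab0_d", 45.0, (30.0, 60.0)),
            FitParameter("slab0_rho", 0.36, (0.34, 0.42)),
            FitParameter("slab0_sigma", 9.0, (0.0, 15.0)),
            FitParameter("slab1_d", 18.0, (12.0, 25.0)),
        ]
        result = fit_stack(curve, preset.stack, params, quick_config(gens=150))
        # converged to the noise floor and recovered the diffuse layer
        noise_floor = (0.02 / np.log(10)) ** 2
        assert result.cost_value < 3 * noise_floor
        assert result.values["slab0_d"] == pytest.approx(45.0, rel=0.05)


class TestUncertainty:
    def _fit(self, noise_sigma, seed=21):
        truth = one_slab_stack()
        curve = simulate_curve(
            truth, default_q_grid(80),
            NoiseModel("relative_gaussian", noise_sigma, seed=seed),
        )
        params = [
            FitParameter("slab0_d", 30.0, (25.0, 35.0)),
            FitParameter("slab0_rho", 0.45, (0.41, 0.49)),
        ]
        config = quick_config(seed=5)
        result = fit_stack(curve, truth, params, config)
        return result, curve, truth, config

    def test_fixed_parameters_report_zero_sigma(self):
        result, curve, truth, config = self._fit(0.02)
        sigma = parameter_uncertainty(result, curve, truth, config, n_boot=15, seed=1)
        assert sigma["slab0_sigma"] == 0.0
        assert sigma["backing_sigma"] == 0.0
        assert sigma["slab0_d"] > 0

    def test_uncertainty_scales_with_noise(self):
        fit_lo, curve_lo, truth_lo, cfg = self._fit(0.01)
        fit_hi, curve_hi, truth_hi, _ = self._fit(0.02)
        s1 = parameter_uncertainty(fit_lo, curve_lo, truth_lo, cfg, n_boot=40, seed=2)
        s2 = parameter_uncertainty(fit_hi, curve_hi, truth_hi, cfg, n_boot=40, seed=2)
        ratio = s2["slab0_d"] / s1["slab0_d"]
        assert 1.0 < ratio < 4.0  # ~2x noise -> ~2x sigma, within 50%

    def test_noiseless_uncertainty_is_tiny(self):
        truth = one_slab_stack()
        curve = simulate_curve(truth, default_q_grid(80))
        params = [FitParameter("slab0_d", 30.0, (25.0, 35.0))]
        config = quick_config(seed=6)
        result = fit_stack(curve, truth, params, config)
        sigma = parameter_uncertainty(result, curve, truth, config, n_boot=15, seed=3)
        assert sigma["slab0_d"] < 1e-4

    def test_too_few_resamples_rejected(self):
        result, curve, truth, config = self._fit(0.02)
        with pytest.raises(ValueError):
            parameter_uncertainty(result, curve, truth, config, n_boot=5)

    def test_bootstrap_reproducible(self):
        result, curve, truth, config = self._fit(0.02)
        s1 = parameter_uncertainty(result, curve, truth, config, n_boot=12, seed=8)
        s2 = parameter_uncertainty(result, curve, truth, config, n_boot=12, seed=8)
        assert s1 == s2


class TestModelComparison:
    def test_identical_costs_select_smaller_model(self):
        truth = one_slab_stack()
        curve = simulate_curve(truth, default_q_grid(60), NoiseModel(seed=1))
        params = [FitParameter("slab0_d", 30.0, (25.0, 35.0))]
        small = fit_stack(curve, truth, params, quick_config(seed=1))
        # a two-slab refit that cannot do better: split of the same layer
        big_template = LayerStack(
            BUFFER, [Slab(15, 0.45, 3.0), Slab(15, 0.45, 0.0)], SILICON, 3.0
        )
        big = fit_stack(
            curve, big_template,
            [FitParameter("slab0_d", 15.0, (10.0, 20.0))],
            quick_config(seed=2),
        )
        big.cost_value = small.cost_value  # exact tie
        selected, report = compare_models(curve, [small, big])
        assert selected is small
        assert report["comparisons"][0]["accepted_larger"] is False

    def test_mismatched_data_rejected(self):
        truth = one_slab_stack()
        c1 = simulate_curve(truth, default_q_grid(60), NoiseModel(seed=1))
        c2 = simulate_curve(truth, default_q_grid(60), NoiseModel(seed=2))
        params = [FitParameter("slab0_d", 30.0, (25.0, 35.0))]
        f1 = fit_stack(c1, truth, params, quick_config())
        f2 = fit_stack(c2, truth, params, quick_config())
        with pytest.raises(ValueError, match="not performed on this curve"):
            compare_models(c1, [f1, f2])


def test_stack_slot_roundtrip():
    stack = make_preset("dopc_monolayer_air").stack
    values = stack_slot_values(stack)
    rebuilt = build_stack(stack, values)
    assert stack_slot_values(rebuilt) == values
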