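"""Optimizer behaviour on analytic cost functions with known solutions."""

import numpy as np
import pytest

from igrtqa import (
    OptimizerConfig,
    one_plus_one,
    regular_step_gd,
    scale_parameters,
    unscale_parameters,
)
from igrtqa.core import ConfigError, InitializationError
from igrtqa.optimizers import StopReason


def quadratic(center):
    c = np.asarray(center, dtype=float)
    return lambda x: float(np.sum((np.asarray(x) - c) ** 2))


class TestRegularStepGD:
    def test_recovers_quadratic_minimum(self):
        cfg = OptimizerConfig(kind="gd")
        best, cost, trace = regular_step_gd(quadratic((3.0, -2.0)), np.array([13.0, 8.0]), cfg)
        assert np.linalg.norm(best - np.array([3.0, -2.0])) <= cfg.min_step * 2
        assert trace.stop_reason in (StopReason.STEP_TOL, StopReason.GRADIENT_TOL)

    def test_stops_immediately_at_minimum(self):
        cfg = OptimizerConfig(kind="gd")
        best, cost, trace = regular_step_gd(quadratic((0.0, 0.0)), np.zeros(2), cfg)
        assert len(trace) == 1
        assert trace.stop_reason == StopReason.GRADIENT_TOL

    def test_step_relaxation_schedule_closed_form(self):
        """1D quadratic with an overshooting step: every iteration reverses the
        gradient, so after k reversals the step is max_step * relaxation**k."""
        cfg = OptimizerConfig(kind="gd", max_step=2.0, relaxation=0.9)
        _, _, trace = regular_step_gd(lambda x: float(x[0] ** 2), np.array([1.0]), cfg)
        accepted = [r for r in trace.records if r.accepted]
        # first iteration has no previous gradient: step stays max_step; each
        # later accepted iteration relaxes once
        for k, rec in enumerate(accepted[:20]):
            assert rec.step == pytest.approx(2.0 * 0.9 ** max(0, k), rel=1e-12)

    def test_invalid_start_raises(self):
        cfg = OptimizerConfig(kind="gd")
        with pytest.raises(InitializationError):
            regular_step_gd(lambda x: float("inf"), np.zeros(2), cfg)

    def test_sentinel_mid_run_rejected_not_raised(self):
        # minimum near an invalid wall: overshooting steps land in the
        # invalid region and must be rejected and halved, not raised
        def cost(x):
            if abs(x[0]) > 6.0:
                return float("inf")
            return float((x[0] - 5.0) ** 2 + x[1] ** 2)

        cfg = OptimizerConfig(kind="gd")
        best, c, trace = regular_step_gd(cost, np.array([-4.0, 0.0]), cfg)
        assert np.isfinite(c)
        assert np.linalg.norm(best - np.array([5.0, 0.0])) < 0.1
        assert any(not r.accepted for r in trace.records)

    def test_trace_bounded_by_max_iter(self):
        cfg = OptimizerConfig(kind="gd", gd_max_iter=200, gradient_tolerance=1e-30,
                              min_step=1e-12)
        # oscillating cost never satisfies tolerances quickly
        _, _, trace = regular_step_gd(lambda x: float(np.sum(np.sin(x) ** 2)) + 1,
                                      np.array([10.0, 3.0]), cfg)
        assert len(trace) <= 200


class TestOnePlusOne:
    def test_seeded_bit_reproducibility(self):
        cfg = OptimizerConfig(kind="evolutionary", seed=42)
        r1 = one_plus_one(quadratic((1.0, 2.0)), np.array([9.0, -9.0]), cfg)
        r2 = one_plus_one(quadratic((1.0, 2.0)), np.array([9.0, -9.0]),
                          OptimizerConfig(kind="evolutionary", seed=42))
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]
        assert [vars(a) for a in r1[2].records] == [vars(b) for b in r2[2].records]

    def test_monte_carlo_convergence_rate(self):
        """Quadratic from (15, 15): at least 95/100 seeds end within 0.1."""
        hits = 0
        for seed in range(100):
            cfg = OptimizerConfig(kind="evolutionary", seed=seed)
            best, _, _ = one_plus_one(quadratic((0.0, 0.0)), np.array([15.0, 15.0]), cfg)
            hits += np.linalg.norm(best) <= 0.1
        assert hits >= 95

    def test_best_cost_sequence_non_increasing(self, rng):
        # rough, multimodal cost: elitist acceptance still never regresses
        def cost(x):
            x = np.asarray(x)
            return float(np.sum(x**2) + 3.0 * np.sum(np.sin(3 * x)))

        cfg = OptimizerConfig(kind="evolutionary", seed=5, evo_max_iter=500)
        _, _, trace = one_plus_one(cost, rng.uniform(-10, 10, 2), cfg)
        assert np.all(np.diff(trace.best_costs) <= 1e-15)
        assert np.all(np.diff(trace.costs) <= 1e-15)  # parent cost is elitist

    def test_trace_bounded_and_radius_stop(self):
        cfg = OptimizerConfig(kind="evolutionary", evo_max_iter=2000)
        _, _, trace = one_plus_one(quadratic((0.0, 0.0)), np.array([1.0, 1.0]), cfg)
        assert len(trace) <= 2000
        assert trace.stop_reason in (StopReason.MAX_ITER, StopReason.RADIUS_EPSILON)

    @pytest.mark.parametrize("rot_scale", [0.25, 0.5, 1.0])
    def test_parameter_scaling_robustness(self, rot_scale):
        cfg = OptimizerConfig(kind="evolutionary", seed=3,
                              parameter_scales=(1.0, 1.0, rot_scale))
        best, _, _ = one_plus_one(quadratic((4.0, -2.0, 1.0)),
                                  np.array([0.0, 0.0, 0.0]), cfg)
        assert np.linalg.norm(best - np.array([4.0, -2.0, 1.0])) <= 0.05


class TestScaling:
    def test_scale_unscale_roundtrip(self, rng):
        raw = rng.uniform(-10, 10, size=(5,))
        scales = (1.0, 1.0, 0.5, 2.0, 0.1)
        back = unscale_parameters(scale_parameters(raw, scales), scales)
        assert np.array_equal(back, raw) or np.max(np.abs(back - raw)) < 1e-15

    def test_mixed_units_example(self):
        assert np.allclose(scale_parameters(np.array([2.0, 2.0, 4.0]), (1, 1, 0.5)),
                           [2.0, 2.0, 2.0])

    def test_invalid_scales_rejected(self):
        with pytest.raises(ConfigError):
            scale_parameters(np.ones(2), (1.0, 0.0))
        with pytest.raises(ConfigError):
            OptimizerConfig(parameter_scales=(1.0, -1.0))

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            OptimizerConfig(min_step=0.5, max_step=0.1)
        with pytest.raises(ConfigError):
            OptimizerConfig(relaxation=1.5)
        with pytest.raises(ConfigError):
            OptimizerConfig(growth_factor=0.5)
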