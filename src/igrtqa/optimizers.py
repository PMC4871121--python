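"""General-purpose minimizers used by the verification registration.

Two optimizers are provided, chosen for their complementary failure
modes: a deterministic regular-step gradient descent and a stochastic
one-plus-one evolutionary strategy that can escape shallow local minima.
Both operate on an arbitrary cost callable over a raw parameter vector
(mm, mm, deg for a rigid registration) and search in a *scaled* space
where one unit of any parameter produces a comparable image displacement,
so a single step-length schedule covers translations and rotations.

Costs equal to ``inf`` (the invalid-point sentinel) are handled inside the
loops — a gradient-descent step onto an invalid point is rejected and the
step halved; an invalid evolutionary child counts as a failed trial — and
are never raised as exceptions mid-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .core import ConfigError, InitializationError

OPTIMIZER_KINDS = ("gd", "evolutionary")


class StopReason(str, Enum):
    MAX_ITER = "MAX_ITER"
    GRADIENT_TOL = "GRADIENT_TOL"
    STEP_TOL = "STEP_TOL"
    RADIUS_EPSILON = "RADIUS_EPSILON"


@dataclass
class OptimizerConfig:
    """Shared configuration for both optimizers.

    Gradient descent: the step length starts at ``max_step`` (scaled
    units), is multiplied by ``relaxation`` whenever the gradient
    direction reverses, and the run stops after ``gd_max_iter``
    iterations, when the step falls below ``min_step``, or when the scaled
    gradient magnitude drops below ``gradient_tolerance``.

    One-plus-one: the mutation radius grows by ``growth_factor`` on every
    accepted child (capped at ``radius_ceiling``) and shrinks by
    ``shrink_factor`` on rejection (default ``growth_factor ** -0.25``);
    the run stops when the radius falls below ``epsilon`` or after
    ``evo_max_iter`` iterations.

    ``parameter_scales`` multiplies raw parameters into scaled units; the
    registration default is 1 per mm and 0.5 per degree.
    """

    kind: str = "evolutionary"
    # regular-step gradient descent
    min_step: float = 0.01
    max_step: float = 2.0
    relaxation: float = 0.9
    gd_max_iter: int = 200
    gradient_tolerance: float = 1e-5
    # one-plus-one evolutionary
    growth_factor: float = 2.0
    shrink_factor: float | None = None
    epsilon: float = 1.5e-6
    evo_max_iter: int = 2000
    initial_radius: float = 1.0
    radius_ceiling: float = 30.0
    # shared
    parameter_scales: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in OPTIMIZER_KINDS:
            raise ConfigError(f"optimizer kind must be one of {OPTIMIZER_KINDS}")
        if not 0 < self.min_step <= self.max_step:
            raise ConfigError("need 0 < min_step <= max_step")
        if not 0 < self.relaxation < 1:
            raise ConfigError("relaxation must be in (0, 1)")
        if self.growth_factor <= 1:
            raise ConfigError("growth_factor must be > 1")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.initial_radius <= 0 or self.radius_ceiling <= 0:
            raise ConfigError("radii must be positive")
        if self.shrink_factor is None:
            self.shrink_factor = self.growth_factor ** -0.25
        if not 0 < self.shrink_factor < 1:
            raise ConfigError("shrink_factor must be in (0, 1)")
        if self.parameter_scales is not None:
            self.parameter_scales = tuple(float(s) for s in self.parameter_scales)
            if any(s <= 0 for s in self.parameter_scales):
                raise ConfigError("parameter scales must be positive")

    def scales_for(self, n: int) -> np.ndarray:
        if self.parameter_scales is None:
            return np.ones(n)
        if len(self.parameter_scales) != n:
            raise ConfigError(
                f"{len(self.parameter_scales)} scales given for {n} parameters"
            )
        return np.asarray(self.parameter_scales, dtype=float)


@dataclass
class TraceRecord:
    iteration: int
    cost: float
    parameters: tuple[float, ...]
    step: float  # step length (GD) or search radius (one-plus-one)
    accepted: bool


@dataclass
class OptimizerTrace:
    """Per-iteration history of one optimizer run."""

    records: list[TraceRecord] = field(default_factory=list)
    stop_reason: StopReason | None = None

    def append(self, iteration, cost, parameters, step, accepted) -> None:
        self.records.append(
            TraceRecord(int(iteration), float(cost), tuple(map(float, parameters)),
                        float(step), bool(accepted))
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def costs(self) -> np.ndarray:
        return np.array([r.cost for r in self.records])

    @property
    def best_costs(self) -> np.ndarray:
        """Best-so-far cost after each iteration (non-increasing)."""
        return np.minimum.accumulate(self.costs) if self.records else np.array([])

    def to_dict(self) -> dict:
        return {
            "stop_reason": self.stop_reason.value if self.stop_reason else None,
            "records": [
                {
                    "iteration": r.iteration,
                    "cost": r.cost,
                    "parameters": list(r.parameters),
                    "step": r.step,
                    "accepted": r.accepted,
                }
                for r in self.records
            ],
        }


def scale_parameters(raw: np.ndarray, scales: Sequence[float]) -> np.ndarray:
    """Element-wise raw -> scaled (multiply)."""
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ConfigError("parameter scales must be positive")
    return np.asarray(raw, dtype=float) * scales


def unscale_parameters(scaled: np.ndarray, scales: Sequence[float]) -> np.ndarray:
    """Element-wise scaled -> raw (divide); exact inverse of scale_parameters."""
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ConfigError("parameter scales must be positive")
    return np.asarray(scaled, dtype=float) / scales


def _finite_gradient(
    cost_scaled: Callable[[np.ndarray], float],
    s: np.ndarray,
    c0: float,
    h: float,
) -> np.ndarray:
    """Central-difference gradient in scaled space.

    When one side of a central difference is invalid the one-sided
    difference through the current cost is used; when both sides are
    invalid that component is zero.
    """
    g = np.zeros_like(s)
    for k in range(s.size):
        e = np.zeros_like(s)
        e[k] = h
        cp = cost_scaled(s + e)
        cm = cost_scaled(s - e)
        if np.isfinite(cp) and np.isfinite(cm):
            g[k] = (cp - cm) / (2 * h)
        elif np.isfinite(cp):
            g[k] = (cp - c0) / h
        elif np.isfinite(cm):
            g[k] = (c0 - cm) / h
    return g


def regular_step_gd(
    cost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: OptimizerConfig | None = None,
) -> tuple[np.ndarray, float, OptimizerTrace]:
    """Regular-step gradient descent with a relaxation step schedule.

    Moves by ``step`` along the negative unit scaled gradient (central
    finite differences with probe ``h = min_step / 10``); the step starts
    at ``max_step`` and is multiplied by ``relaxation`` each time the
    gradient direction reverses (negative dot product with the previous
    gradient).  Returns the best point evaluated, its cost, and the trace.
    """
    cfg = config or OptimizerConfig(kind="gd")
    x0 = np.asarray(x0, dtype=float)
    scales = cfg.scales_for(x0.size)

    def cost_scaled(s: np.ndarray) -> float:
        return cost(unscale_parameters(s, scales))

    s = scale_parameters(x0, scales)
    c = cost_scaled(s)
    if not np.isfinite(c):
        raise InitializationError(
            "cost is invalid at the starting point; choose a different x0"
        )
    trace = OptimizerTrace()
    best_s, best_c = s.copy(), c
    h = cfg.min_step / 10.0
    step = cfg.max_step
    g_prev: np.ndarray | None = None

    for it in range(1, cfg.gd_max_iter + 1):
        g = _finite_gradient(cost_scaled, s, c, h)
        gnorm = float(np.linalg.norm(g))
        if gnorm < cfg.gradient_tolerance:
            trace.append(it, c, unscale_parameters(s, scales), step, False)
            trace.stop_reason = StopReason.GRADIENT_TOL
            break
        if g_prev is not None and float(np.dot(g, g_prev)) < 0.0:
            step *= cfg.relaxation
        if step < cfg.min_step:
            trace.append(it, c, unscale_parameters(s, scales), step, False)
            trace.stop_reason = StopReason.STEP_TOL
            break
        s_new = s - step * g / gnorm
        c_new = cost_scaled(s_new)
        if not np.isfinite(c_new):
            # invalid point: reject the move and halve the step
            step *= 0.5
            trace.append(it, c, unscale_parameters(s, scales), step, False)
            if step < cfg.min_step:
                trace.stop_reason = StopReason.STEP_TOL
                break
            continue
        s, c, g_prev = s_new, c_new, g
        trace.append(it, c, unscale_parameters(s, scales), step, True)
        if c < best_c:
            best_c, best_s = c, s.copy()
    else:
        trace.stop_reason = StopReason.MAX_ITER
    if trace.stop_reason is None:  # loop broke without setting a reason
        trace.stop_reason = StopReason.STEP_TOL
    return unscale_parameters(best_s, scales), best_c, trace


def one_plus_one(
    cost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: OptimizerConfig | None = None,
) -> tuple[np.ndarray, float, OptimizerTrace]:
    """One-plus-one evolutionary strategy (elitist (1+1)-ES).

    A single parent is perturbed by an isotropic Gaussian of radius ``r``
    in scaled space.  A better child replaces the parent and the radius
    grows by ``growth_factor`` (more aggressive search); otherwise the
    radius shrinks by ``shrink_factor``.  Fully reproducible given
    ``config.seed``.
    """
    cfg = config or OptimizerConfig(kind="evolutionary")
    x0 = np.asarray(x0, dtype=float)
    scales = cfg.scales_for(x0.size)

    def cost_scaled(s: np.ndarray) -> float:
        return cost(unscale_parameters(s, scales))

    rng = np.random.default_rng(cfg.seed)
    parent = scale_parameters(x0, scales)
    parent_cost = cost_scaled(parent)
    if not np.isfinite(parent_cost):
        raise InitializationError(
            "cost is invalid at the starting point; choose a different x0"
        )
    trace = OptimizerTrace()
    r = cfg.initial_radius

    for it in range(1, cfg.evo_max_iter + 1):
        if r < cfg.epsilon:
            trace.stop_reason = StopReason.RADIUS_EPSILON
            break
        child = parent + r * rng.standard_normal(parent.size)
        child_cost = cost_scaled(child)
        accepted = np.isfinite(child_cost) and child_cost < parent_cost
        if accepted:
            parent, parent_cost = child, child_cost
            r = min(r * cfg.growth_factor, cfg.radius_ceiling)
        else:
            r *= cfg.shrink_factor
        trace.append(it, parent_cost, unscale_parameters(parent, scales), r, accepted)
    else:
        trace.stop_reason = StopReason.MAX_ITER
    if trace.stop_reason is None:
        trace.stop_reason = StopReason.RADIUS_EPSILON
    return unscale_parameters(parent, scales), parent_cost, trace


def minimize(
    cost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: OptimizerConfig,
) -> tuple[np.ndarray, float, OptimizerTrace]:
    """Dispatch to the optimizer selected by ``config.kind``."""
    if config.kind == "gd":
        return regular_step_gd(cost, x0, config)
    return one_plus_one(cost, x0, config)
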