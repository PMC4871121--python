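"""Registration orchestration: single runs, multistart studies, and the
fusion of two orthogonal planar solutions into a 5-DOF couch correction.

The verification registration deliberately re-solves the alignment with
its own metric/optimizer configuration so that agreement with the
clinical system is an independent check, not a replay.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    CouchCorrection,
    InitializationError,
    ProjectionImage,
    RigidTransform2D,
)
from .geometry import MIN_OVERLAP_FRACTION, overlap_fraction, resample
from .metrics import MetricSpec, PairCost
from .optimizers import OptimizerConfig, OptimizerTrace, minimize
from .preprocess import HistogramMatchConfig

#: Default scaled units per raw unit for (tx mm, ty mm, theta deg): one
#: scaled unit of rotation corresponds to the displacement a degree of
#: couch rotation induces roughly 30 mm off-centre.
DEFAULT_PARAMETER_SCALES = (1.0, 1.0, 0.5)


def _fingerprint(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RegistrationResult:
    """Outcome of one verification registration."""

    transform: RigidTransform2D
    final_cost: float
    trace: OptimizerTrace
    preprocess_applied: bool
    config_fingerprint: str
    metric_kind: str
    optimizer_kind: str
    x0: RigidTransform2D

    def to_dict(self, include_trace: bool = True) -> dict:
        d = {
            "transform": {
                "tx": self.transform.tx,
                "ty": self.transform.ty,
                "theta": self.transform.theta,
                "center": list(self.transform.center),
            },
            "final_cost": self.final_cost,
            "stop_reason": self.trace.stop_reason.value if self.trace.stop_reason else None,
            "n_iterations": len(self.trace),
            "preprocess_applied": self.preprocess_applied,
            "config_fingerprint": self.config_fingerprint,
            "metric": self.metric_kind,
            "optimizer": self.optimizer_kind,
            "x0": {"tx": self.x0.tx, "ty": self.x0.ty, "theta": self.x0.theta},
        }
        if include_trace:
            d["trace"] = self.trace.to_dict()
        return d

    def to_json(self, include_trace: bool = True) -> str:
        return json.dumps(self.to_dict(include_trace), sort_keys=True)


def _resolve_config(
    metric: MetricSpec | None, opt: OptimizerConfig | None
) -> tuple[MetricSpec, OptimizerConfig]:
    metric = metric or MetricSpec()
    opt = opt or OptimizerConfig()
    if opt.parameter_scales is None:
        opt.parameter_scales = DEFAULT_PARAMETER_SCALES
    return metric, opt


def register_pair(
    fixed: ProjectionImage,
    moving: ProjectionImage,
    metric: MetricSpec | None = None,
    opt: OptimizerConfig | None = None,
    x0: RigidTransform2D | None = None,
    preprocess: bool = True,
    hm_config: HistogramMatchConfig | None = None,
    center: tuple[float, float] | None = None,
) -> RegistrationResult:
    """Register ``moving`` onto ``fixed`` over (tx, ty, theta).

    Histogram matching (moving onto fixed) and [0, 1] normalization are
    applied once before optimization.  The rotation centre defaults to the
    fixed image's physical centre; ``x0`` defaults to the identity.

    Raises :class:`InitializationError` when the starting transform leaves
    less than the minimum valid overlap.
    """
    metric, opt = _resolve_config(metric, opt)
    if center is None:
        center = fixed.physical_center
    if x0 is None:
        x0 = RigidTransform2D.identity(center)
    elif x0.center != center:
        x0 = x0.with_center(center)

    pair_cost = PairCost(
        fixed, moving, metric, preprocess=preprocess, hm_config=hm_config
    )
    _check_start(pair_cost, x0)

    def cost(v: np.ndarray) -> float:
        return pair_cost(RigidTransform2D.from_vector(v, center))

    best, best_cost, trace = minimize(cost, x0.as_vector(), opt)
    fingerprint = _fingerprint(
        {
            "metric": vars(metric),
            "optimizer": vars(opt),
            "preprocess": preprocess,
            "hm": vars(hm_config) if hm_config else None,
            "center": center,
        }
    )
    return RegistrationResult(
        transform=RigidTransform2D.from_vector(best, center),
        final_cost=float(best_cost),
        trace=trace,
        preprocess_applied=preprocess,
        config_fingerprint=fingerprint,
        metric_kind=metric.kind,
        optimizer_kind=opt.kind,
        x0=x0,
    )


def _check_start(pair_cost: PairCost, x0: RigidTransform2D) -> None:
    try:
        _, mask = resample(pair_cost.moving, x0, pair_cost.fixed)
        frac = overlap_fraction(mask)
    except Exception as exc:
        raise InitializationError(f"starting transform is degenerate: {exc}") from exc
    if frac < MIN_OVERLAP_FRACTION:
        raise InitializationError(
            f"starting transform leaves only {frac:.0%} overlap "
            f"(need >= {MIN_OVERLAP_FRACTION:.0%}); choose a different x0"
        )
    if not np.isfinite(pair_cost(x0)):
        raise InitializationError("metric is degenerate at the starting transform")


@dataclass
class MultistartSummary:
    """Consensus statistics across multistart registrations."""

    mean_cost: float
    std_cost: float
    max_pairwise_translation_mm: float
    max_pairwise_rotation_deg: float

    def to_dict(self) -> dict:
        return vars(self).copy()


def _start_transforms(
    n_starts: int,
    offset_radius: float,
    rotation_offset: float,
    seed: int,
    center: tuple[float, float],
    around: RigidTransform2D,
    mode: str,
) -> list[RigidTransform2D]:
    rng = np.random.default_rng(seed)
    starts = []
    for k in range(n_starts):
        if mode == "circle":
            ang = 2 * math.pi * (k + rng.random()) / n_starts if n_starts > 1 else \
                2 * math.pi * rng.random()
            dx, dy = offset_radius * math.cos(ang), offset_radius * math.sin(ang)
        else:  # uniform in the disc
            r = offset_radius * math.sqrt(rng.random())
            ang = 2 * math.pi * rng.random()
            dx, dy = r * math.cos(ang), r * math.sin(ang)
        dth = rng.uniform(-rotation_offset, rotation_offset) if rotation_offset else 0.0
        starts.append(
            RigidTransform2D(around.tx + dx, around.ty + dy, around.theta + dth, center)
        )
    return starts


def multistart(
    fixed: ProjectionImage,
    moving: ProjectionImage,
    metric: MetricSpec | None = None,
    opt: OptimizerConfig | None = None,
    n_starts: int = 10,
    offset_radius: float = 20.0,
    rotation_offset: float = 0.0,
    seed: int = 0,
    around: RigidTransform2D | None = None,
    mode: str = "ball",
    preprocess: bool = True,
    hm_config: HistogramMatchConfig | None = None,
) -> tuple[list[RegistrationResult], MultistartSummary]:
    """Run ``n_starts`` registrations from perturbed initial positions.

    Starts are placed around ``around`` (identity by default): uniformly
    in a disc of ``offset_radius`` mm (``mode='ball'``) or evenly on the
    circle of that radius (``mode='circle'``).  Each run's evolutionary
    seed is derived deterministically from ``seed``.
    """
    if n_starts < 2:
        raise ValueError("multistart needs n_starts >= 2")
    metric, opt = _resolve_config(metric, opt)
    center = fixed.physical_center
    if around is None:
        around = RigidTransform2D.identity(center)
    starts = _start_transforms(
        n_starts, offset_radius, rotation_offset, seed, center, around, mode
    )
    results = []
    for x0 in starts:
        results.append(
            register_pair(fixed, moving, metric, opt, x0=x0,
                          preprocess=preprocess, hm_config=hm_config)
        )
    costs = np.array([r.final_cost for r in results])
    sols = np.array([r.transform.as_vector() for r in results])
    dt = sols[:, None, :2] - sols[None, :, :2]
    max_t = float(np.max(np.abs(dt))) if n_starts > 1 else 0.0
    dth = sols[:, None, 2] - sols[None, :, 2]
    summary = MultistartSummary(
        mean_cost=float(costs.mean()),
        std_cost=float(costs.std(ddof=1)),
        max_pairwise_translation_mm=max_t,
        max_pairwise_rotation_deg=float(np.max(np.abs(dth))),
    )
    return results, summary


def fuse_orthogonal(
    ap: RegistrationResult | RigidTransform2D,
    lateral: RegistrationResult | RigidTransform2D,
) -> tuple[CouchCorrection, float]:
    """Fuse AP and lateral planar solutions into one couch correction.

    View convention: in the AP image, x is the patient's lateral axis and
    y the longitudinal axis, with in-plane rotation equal to couch yaw; in
    the lateral image, x is longitudinal and y vertical, with in-plane
    rotation equal to couch pitch.  The longitudinal shift is observed in
    both views; the fused value is their mean and the absolute
    disagreement between the two observations is returned as a
    consistency diagnostic (mm).
    """
    t_ap = ap.transform if isinstance(ap, RegistrationResult) else ap
    t_lat = lateral.transform if isinstance(lateral, RegistrationResult) else lateral
    long_ap = t_ap.ty
    long_lat = t_lat.tx
    couch = CouchCorrection(
        vert=t_lat.ty,
        lat=t_ap.tx,
        long=0.5 * (long_ap + long_lat),
        rotation=t_ap.theta,
        pitch=t_lat.theta,
    )
    return couch, abs(long_ap - long_lat)
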