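"""Cost-function landscape diagnostics.

An exhaustive map of the metric over in-plane translations (rotation held
at zero) makes the optimization problem visible: a usable metric shows a
single prominent basin at the true shift with smooth isocontours, while
an unusable one is flat, multi-modal, or has its optimum in the wrong
place.  Two quantitative diagnostics summarize a map: the number of
strict local minima (multi-modality — poison for a gradient follower)
and the width of the global basin (how sharply the optimum is defined).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ProjectionImage, RigidTransform2D
from .metrics import MetricSpec, PairCost
from .preprocess import HistogramMatchConfig

log = logging.getLogger(__name__)


@dataclass
class SearchSpaceMap:
    """Metric values over a regular (tx, ty) translation grid.

    ``costs[i, j]`` is the metric at ``ty_values[i]``, ``tx_values[j]``;
    invalid points carry ``inf``.
    """

    costs: np.ndarray
    tx_values: np.ndarray
    ty_values: np.ndarray
    step: float
    metric_kind: str
    preprocess_applied: bool

    @property
    def argmin(self) -> tuple[float, float]:
        """(tx, ty) in mm of the lowest-cost grid node."""
        i, j = np.unravel_index(np.argmin(self.costs), self.costs.shape)
        return float(self.tx_values[j]), float(self.ty_values[i])

    def to_dict(self) -> dict:
        return {
            "tx_values": self.tx_values.tolist(),
            "ty_values": self.ty_values.tolist(),
            "step": self.step,
            "metric": self.metric_kind,
            "preprocess": self.preprocess_applied,
            "costs": [[None if not np.isfinite(c) else c for c in row]
                      for row in self.costs],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def map_search_space(
    fixed: ProjectionImage,
    moving: ProjectionImage,
    metric: MetricSpec | None = None,
    tx_range: tuple[float, float] = (-30.0, 30.0),
    ty_range: tuple[float, float] = (-30.0, 30.0),
    step: float = 1.0,
    with_preprocess: bool = True,
    hm_config: HistogramMatchConfig | None = None,
) -> SearchSpaceMap:
    """Evaluate the metric at every node of a translation grid (theta = 0).

    Preprocessing is applied once when enabled; each node is one
    resample + metric evaluation, so the default 61x61 grid costs 3721
    evaluations per metric.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if tx_range[0] > tx_range[1] or ty_range[0] > ty_range[1]:
        raise ValueError("ranges must be ordered (low, high)")
    metric = metric or MetricSpec()
    pair_cost = PairCost(fixed, moving, metric, preprocess=with_preprocess,
                         hm_config=hm_config)
    center = fixed.physical_center
    tx_values = np.arange(tx_range[0], tx_range[1] + 0.5 * step, step)
    ty_values = np.arange(ty_range[0], ty_range[1] + 0.5 * step, step)
    costs = np.empty((ty_values.size, tx_values.size))
    for i, ty in enumerate(ty_values):
        for j, tx in enumerate(tx_values):
            costs[i, j] = pair_cost(RigidTransform2D(float(tx), float(ty), 0.0, center))
    return SearchSpaceMap(costs, tx_values, ty_values, float(step),
                          metric.kind, bool(with_preprocess))


def default_depth_tolerance(m: SearchSpaceMap) -> float:
    """1% of the finite cost range of the map."""
    finite = m.costs[np.isfinite(m.costs)]
    return 0.01 * float(finite.max() - finite.min()) if finite.size else 0.0


def local_minima(
    m: SearchSpaceMap, depth_tolerance: float | None = None
) -> list[tuple[float, float]]:
    """(tx, ty) of every interior node strictly below all 8 neighbours.

    A node counts as a local minimum only when it undercuts each
    neighbour by more than ``depth_tolerance`` (default: 1% of the map's
    cost range), so sub-tolerance noise ripples are ignored.  Border
    nodes are excluded.
    """
    if depth_tolerance is None:
        depth_tolerance = default_depth_tolerance(m)
    c = m.costs
    coords = []
    for i in range(1, c.shape[0] - 1):
        for j in range(1, c.shape[1] - 1):
            v = c[i, j]
            if not np.isfinite(v):
                continue
            neigh = c[i - 1:i + 2, j - 1:j + 2].ravel()
            neigh = np.delete(neigh, 4)
            if np.all(v < neigh - depth_tolerance):
                coords.append((float(m.tx_values[j]), float(m.ty_values[i])))
    return coords


def count_local_minima(m: SearchSpaceMap, depth_tolerance: float | None = None) -> int:
    return len(local_minima(m, depth_tolerance))


def minima_tolerance_sweep(
    m: SearchSpaceMap, fractions=(0.002, 0.005, 0.01, 0.02, 0.05)
) -> dict[float, int]:
    """Local-minima counts across a sweep of depth tolerances (as fractions
    of the map's cost range)."""
    finite = m.costs[np.isfinite(m.costs)]
    rng_ = float(finite.max() - finite.min())
    return {f: count_local_minima(m, f * rng_) for f in fractions}


def basin_width(m: SearchSpaceMap, fraction: float = 0.1) -> tuple[float, float]:
    """Extent (mm) in x and y of the global basin.

    The basin is the connected grid region around the global minimum
    whose cost lies within ``fraction`` of the map's cost range above the
    minimum.  With several equal global minima the widest basin is
    returned and a warning logged.
    """
    finite = m.costs[np.isfinite(m.costs)]
    lo, hi = float(finite.min()), float(finite.max())
    threshold = lo + fraction * (hi - lo)
    within = np.isfinite(m.costs) & (m.costs <= threshold)
    labels, n_comp = ndimage.label(within)
    minima_mask = m.costs == lo
    basin_labels = np.unique(labels[minima_mask])
    basin_labels = basin_labels[basin_labels > 0]
    if minima_mask.sum() > 1:
        log.warning("basin_width: %d equal global minima; reporting the widest basin",
                    int(minima_mask.sum()))
    best = (0.0, 0.0)
    for lab in basin_labels:
        ii, jj = np.nonzero(labels == lab)
        wx = (jj.max() - jj.min() + 1) * m.step
        wy = (ii.max() - ii.min() + 1) * m.step
        if wx * wy >= best[0] * best[1]:
            best = (float(wx), float(wy))
    return best


def plot_map(m: SearchSpaceMap, path, n_contours: int = 12) -> None:
    """Render the map as a heatmap with isocontour overlays (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = np.where(np.isfinite(m.costs), m.costs, np.nan)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    extent = [m.tx_values[0], m.tx_values[-1], m.ty_values[-1], m.ty_values[0]]
    im = ax.imshow(finite, extent=extent, aspect="equal", cmap="jet")
    with np.errstate(invalid="ignore"):
        ax.contour(m.tx_values, m.ty_values, finite, levels=n_contours,
                   colors="k", linewidths=0.5)
    ax.set_xlabel("tx (mm)")
    ax.set_ylabel("ty (mm)")
    pp = "with" if m.preprocess_applied else "without"
    ax.set_title(f"{m.metric_kind} search space ({pp} histogram matching)")
    fig.colorbar(im, ax=ax, label="cost")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
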