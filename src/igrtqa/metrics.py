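"""Similarity metrics for planar DRR/kV registration.

Three cost functions are provided, all with the convention *lower is
better*, all averaged over the valid overlap mask so that their values are
comparable across overlap sizes:

* ``ncc`` — negated Pearson correlation of the masked pixel pairs; assumes
  a linear intensity relation between the two images.  Range [-1, 1].
* ``gradient_difference`` — mean squared difference of the central-
  difference image gradients (row and column), sensitive to organ borders
  and invariant to constant intensity offsets.  Range [0, inf).
* ``mrsd`` — mean reciprocal squared difference,
  ``-(1/N) sum 1 / (1 + (A_i - B_i)^2 / lambda^2)``: each pixel pair
  contributes through a Lorentzian window of capture radius ``lambda``,
  which sharpens sensitivity near the global minimum.  Range (-1, 0].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    ConfigError,
    DegenerateMetricError,
    DegenerateOverlapError,
    ProjectionImage,
    RigidTransform2D,
)
from .geometry import MIN_OVERLAP_FRACTION, overlap_fraction, resample
from .preprocess import HistogramMatchConfig, histogram_match, normalize

METRIC_KINDS = ("ncc", "graddiff", "mrsd")

#: Sentinel cost returned for invalid parameter points (degenerate overlap
#: or undefined metric); optimizers treat it as "infinitely bad", never as
#: an exception.
INVALID_COST = np.inf


@dataclass(frozen=True)
class MetricSpec:
    """Choice of cost function plus its options.

    ``lambda_capture`` is the MRSD capture radius in normalized intensity
    units; ``roi`` is an optional rectangular region of interest
    ``(row_start, row_stop, col_start, col_stop)`` in reference pixels;
    ``normalized_graddiff`` switches the gradient metric to the
    variance-normalized reciprocal variant from the broader literature.
    """

    kind: str = "ncc"
    lambda_capture: float = 0.1
    roi: tuple[int, int, int, int] | None = None
    normalized_graddiff: bool = False

    def __post_init__(self) -> None:
        if self.kind not in METRIC_KINDS:
            raise ConfigError(f"metric kind must be one of {METRIC_KINDS}, got {self.kind!r}")
        if self.lambda_capture <= 0:
            raise ConfigError(f"lambda_capture must be positive, got {self.lambda_capture}")


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ProjectionImage) else np.asarray(img, dtype=float)


def _full_mask(arr: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(arr.shape, dtype=bool)
    return np.asarray(mask, dtype=bool)


def ncc(fixed, moving_resampled, mask: np.ndarray | None = None) -> float:
    """Negated normalized cross correlation over the masked pixels.

    Returns -1 exactly when the two masked intensity sets are related by a
    positive linear map.  Raises :class:`DegenerateMetricError` when either
    image is constant over the mask (correlation undefined).
    """
    a = _pixels(fixed)
    b = _pixels(moving_resampled)
    m = _full_mask(a, mask)
    av = a[m]
    bv = b[m]
    if av.size < 2:
        raise DegenerateMetricError("NCC needs at least two masked pixels")
    ac = av - av.mean()
    bc = bv - bv.mean()
    na = np.sqrt(np.dot(ac, ac))
    nb = np.sqrt(np.dot(bc, bc))
    if na == 0.0 or nb == 0.0:
        raise DegenerateMetricError("NCC undefined: constant image over the mask")
    return float(-np.dot(ac, bc) / (na * nb))


def _interior_mask(mask: np.ndarray) -> np.ndarray:
    """Masked pixels whose 4-neighbourhood is masked, excluding the border."""
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    return interior


def gradient_difference(
    fixed,
    moving_resampled,
    mask: np.ndarray | None = None,
    spacing: tuple[float, float] = (1.0, 1.0),
    normalized: bool = False,
) -> float:
    """Mean squared difference of central-difference gradients.

    ``normalized=True`` selects the reciprocal-variance variant
    ``-(1/N) sum_d sigma_d^2 / (sigma_d^2 + diff_d^2)`` (lower is better),
    where ``sigma_d^2`` is the variance of the fixed image's gradient in
    direction ``d``.
    """
    a = _pixels(fixed)
    b = _pixels(moving_resampled)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise DegenerateMetricError("gradient difference needs at least a 3x3 image")
    m = _full_mask(a, mask)
    interior = _interior_mask(m)
    if not interior.any():
        raise DegenerateMetricError("gradient difference: mask has no interior pixels")
    ga_r, ga_c = np.gradient(a, spacing[0], spacing[1])
    gb_r, gb_c = np.gradient(b, spacing[0], spacing[1])
    dr = ga_r[interior] - gb_r[interior]
    dc = ga_c[interior] - gb_c[interior]
    if not normalized:
        return float(np.mean(dr**2 + dc**2))
    var_r = float(np.var(ga_r[interior]))
    var_c = float(np.var(ga_c[interior]))
    if var_r == 0.0 and var_c == 0.0:
        raise DegenerateMetricError("normalized gradient difference: flat fixed image")
    term_r = var_r / (var_r + dr**2) if var_r > 0 else np.zeros_like(dr)
    term_c = var_c / (var_c + dc**2) if var_c > 0 else np.zeros_like(dc)
    return float(-np.mean(term_r + term_c))


def mrsd(
    fixed,
    moving_resampled,
    mask: np.ndarray | None = None,
    lambda_capture: float = 0.1,
) -> float:
    """Mean reciprocal squared difference with capture radius ``lambda_capture``."""
    if lambda_capture <= 0:
        raise ConfigError("lambda_capture must be positive")
    a = _pixels(fixed)
    b = _pixels(moving_resampled)
    m = _full_mask(a, mask)
    if not m.any():
        raise DegenerateMetricError("MRSD: empty mask")
    d = a[m] - b[m]
    return float(-np.mean(1.0 / (1.0 + (d / lambda_capture) ** 2)))


def _dispatch(spec: MetricSpec, fixed_arr, moving_arr, mask, spacing) -> float:
    if spec.kind == "ncc":
        return ncc(fixed_arr, moving_arr, mask)
    if spec.kind == "graddiff":
        return gradient_difference(
            fixed_arr, moving_arr, mask, spacing=spacing, normalized=spec.normalized_graddiff
        )
    return mrsd(fixed_arr, moving_arr, mask, lambda_capture=spec.lambda_capture)


def _roi_mask(shape: tuple[int, int], roi) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    r0, r1, c0, c1 = roi
    m[r0:r1, c0:c1] = True
    return m


class PairCost:
    """Cost of a rigid transform for one fixed/moving image pair.

    Preprocessing (histogram matching of the moving image onto the fixed,
    then normalization of both to [0, 1]) is applied once at construction
    and cached, so that repeated evaluations during optimization or
    landscape mapping only pay for resampling and the metric itself.

    Calling the object with a transform returns the metric value, or the
    :data:`INVALID_COST` sentinel for degenerate parameter points
    (overlap below ``min_overlap`` of the reference, or an undefined
    metric value).
    """

    def __init__(
        self,
        fixed: ProjectionImage,
        moving: ProjectionImage,
        spec: MetricSpec | None = None,
        preprocess: bool = True,
        hm_config: HistogramMatchConfig | None = None,
        min_overlap: float = MIN_OVERLAP_FRACTION,
    ) -> None:
        self.spec = spec or MetricSpec()
        self.preprocess = bool(preprocess)
        self.min_overlap = float(min_overlap)
        if self.preprocess:
            moving = histogram_match(moving, fixed, hm_config)
            fixed = normalize(fixed)
            moving = normalize(moving)
        self.fixed = fixed
        self.moving = moving
        self._roi = (
            _roi_mask(fixed.shape, self.spec.roi) if self.spec.roi is not None else None
        )

    def __call__(self, transform: RigidTransform2D) -> float:
        try:
            resampled, mask = resample(self.moving, transform, self.fixed)
        except DegenerateOverlapError:
            return INVALID_COST
        if overlap_fraction(mask) < self.min_overlap:
            return INVALID_COST
        if self._roi is not None:
            mask = mask & self._roi
            if not mask.any():
                return INVALID_COST
        try:
            return _dispatch(
                self.spec, self.fixed, resampled, mask, self.fixed.spacing
            )
        except DegenerateMetricError:
            return INVALID_COST


def evaluate(
    spec: MetricSpec,
    fixed: ProjectionImage,
    moving: ProjectionImage,
    transform: RigidTransform2D,
    preprocess: bool = True,
    hm_config: HistogramMatchConfig | None = None,
) -> float:
    """One-shot metric evaluation at a single transform.

    Convenience wrapper over :class:`PairCost`; prefer constructing a
    :class:`PairCost` when evaluating many transforms on the same pair.
    """
    return PairCost(fixed, moving, spec, preprocess=preprocess, hm_config=hm_config)(
        transform
    )
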