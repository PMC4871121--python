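"""Rigid resampling of projection images.

Resampling evaluates the moving image at transformed reference-grid
positions with bilinear interpolation.  Sample points that fall outside
the moving image are recorded in an overlap mask and excluded from metric
evaluation rather than zero-filled, so that large shifts cannot be
rewarded for comparing anatomy against padding.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DegenerateOverlapError, ProjectionImage, RigidTransform2D
from .core import compose as compose  # re-exported: composition is a geometric op

# Minimum fraction of reference pixels that must land inside the moving
# image for a metric evaluation to be meaningful.
MIN_OVERLAP_FRACTION = 0.25


def resample(
    moving: ProjectionImage,
    transform: RigidTransform2D,
    reference: ProjectionImage,
) -> tuple[ProjectionImage, np.ndarray]:
    """Resample ``moving`` under ``transform`` onto ``reference``'s grid.

    Each reference pixel centre ``q`` is mapped to ``transform(q)`` and the
    moving image is sampled there bilinearly.

    Returns
    -------
    (image, mask)
        The resampled image on the reference grid and a boolean overlap
        mask, True where the sample point fell inside the moving image.

    Raises
    ------
    DegenerateOverlapError
        If no sample point lands inside the moving image.
    """
    X, Y = reference.pixel_coordinates()
    pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
    mapped = transform.apply(pts)
    rows, cols = _physical_to_index(moving, mapped)

    n_rows, n_cols = moving.shape
    mask = (rows >= 0) & (rows <= n_rows - 1) & (cols >= 0) & (cols <= n_cols - 1)
    if not mask.any():
        raise DegenerateOverlapError(
            "transform maps every reference pixel outside the moving image"
        )
    values = ndimage.map_coordinates(
        moving.pixels, [rows, cols], order=1, mode="constant", cval=0.0
    )
    values[~mask] = 0.0
    out = ProjectionImage(
        pixels=values.reshape(reference.shape),
        spacing=reference.spacing,
        origin=reference.origin,
        modality=moving.modality,
    )
    return out, mask.reshape(reference.shape)


def _physical_to_index(image: ProjectionImage, points: np.ndarray):
    """Convert (x, y) mm points to fractional (row, col) indices."""
    cols = (points[..., 0] - image.origin[0]) / image.spacing[1]
    rows = (points[..., 1] - image.origin[1]) / image.spacing[0]
    return rows, cols


def overlap_fraction(mask: np.ndarray) -> float:
    return float(np.count_nonzero(mask)) / mask.size
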