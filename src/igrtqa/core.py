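"""Domain types for planar setup-verification registration.

All geometry is expressed in physical millimetres: ``x`` runs along the
column direction, ``y`` along the row direction, and the origin is the
centre of pixel ``(0, 0)``.  Transforms act in physical space so that
anisotropic pixel spacing is handled once, at resampling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

MODALITIES = ("DRR", "KV", "SYNTHETIC")


class ImageFormatError(ValueError):
    """Raised when a raster file cannot be interpreted as a projection image."""


class CouchRecordError(ValueError):
    """Raised when a couch-correction record is malformed."""


class DegenerateOverlapError(RuntimeError):
    """Raised when a transform leaves no valid overlap between two images."""


class DegenerateMetricError(RuntimeError):
    """Raised when a similarity metric is undefined (e.g. constant image)."""


class InitializationError(RuntimeError):
    """Raised when an optimization cannot start from the supplied position."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class ProjectionImage:
    """A 2D projection radiograph (DRR or kV) with physical pixel spacing.

    Parameters
    ----------
    pixels
        Real-valued intensity grid, row-major, at least 8x8.
    spacing
        ``(row_mm, col_mm)`` physical size of one pixel; strictly positive.
    origin
        ``(x_mm, y_mm)`` physical position of the centre of pixel (0, 0).
    modality
        One of ``DRR``, ``KV`` or ``SYNTHETIC``.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] = (0.0, 0.0)
    modality: str = "SYNTHETIC"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ImageFormatError("pixel grid must be two-dimensional")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ImageFormatError(
                f"image must be at least 8x8 pixels, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ImageFormatError("image contains NaN or infinite intensities")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ImageFormatError(f"pixel spacing must be positive, got {self.spacing}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.modality not in MODALITIES:
            raise ImageFormatError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def physical_center(self) -> tuple[float, float]:
        """Physical (x, y) of the grid centre in mm."""
        n_rows, n_cols = self.pixels.shape
        cx = self.origin[0] + 0.5 * (n_cols - 1) * self.spacing[1]
        cy = self.origin[1] + 0.5 * (n_rows - 1) * self.spacing[0]
        return (cx, cy)

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (X, Y) coordinate arrays for every pixel centre."""
        n_rows, n_cols = self.pixels.shape
        x = self.origin[0] + np.arange(n_cols) * self.spacing[1]
        y = self.origin[1] + np.arange(n_rows) * self.spacing[0]
        return np.meshgrid(x, y)

    def with_pixels(self, pixels: np.ndarray) -> "ProjectionImage":
        """Copy of this image with new intensities on the same grid."""
        return ProjectionImage(
            pixels=np.asarray(pixels, dtype=np.float64),
            spacing=self.spacing,
            origin=self.origin,
            modality=self.modality,
        )


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: rotate by ``theta`` about ``center``, then translate.

    A point ``p`` maps to ``R(theta) (p - c) + c + t`` with ``t = (tx, ty)`` in
    mm and ``theta`` in degrees (counter-clockwise in (x, y)).
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for v in (self.tx, self.ty, self.theta, *self.center):
            if not math.isfinite(v):
                raise ConfigError("transform parameters must be finite")

    @classmethod
    def identity(cls, center: tuple[float, float] = (0.0, 0.0)) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0, center)

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        cx, cy = self.center
        # R(p - c) + c + t  ==  R p + (c + t - R c)
        ox = cx + self.tx - (c * cx - s * cy)
        oy = cy + self.ty - (s * cx + c * cy)
        return np.array([[c, -s, ox], [s, c, oy], [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (..., 2) array of (x, y) points in mm."""
        pts = np.asarray(points, dtype=np.float64)
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        cx, cy = self.center
        x = pts[..., 0] - cx
        y = pts[..., 1] - cy
        out = np.empty_like(pts)
        out[..., 0] = c * x - s * y + cx + self.tx
        out[..., 1] = s * x + c * y + cy + self.ty
        return out

    def inverse(self) -> "RigidTransform2D":
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        # inverse about the same centre: theta' = -theta, t' = -R^T t
        tx = -(c * self.tx + s * self.ty)
        ty = -(-s * self.tx + c * self.ty)
        return RigidTransform2D(tx, ty, -self.theta, self.center)

    def with_center(self, center: tuple[float, float]) -> "RigidTransform2D":
        """Equivalent transform re-expressed about a different rotation centre."""
        m = self.matrix()
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        cx, cy = center
        # solve t from  R p + offset = R(p - c') + c' + t
        tx = m[0, 2] - (cx - (c * cx - s * cy))
        ty = m[1, 2] - (cy - (s * cx + c * cy))
        return RigidTransform2D(tx, ty, self.theta, (cx, cy))

    def as_vector(self) -> np.ndarray:
        """Parameter vector (tx mm, ty mm, theta deg)."""
        return np.array([self.tx, self.ty, self.theta])

    @classmethod
    def from_vector(
        cls, v: np.ndarray, center: tuple[float, float] = (0.0, 0.0)
    ) -> "RigidTransform2D":
        return cls(float(v[0]), float(v[1]), float(v[2]), center)

    def replace(self, **kwargs) -> "RigidTransform2D":
        return replace(self, **kwargs)


def compose(a: RigidTransform2D, b: RigidTransform2D) -> RigidTransform2D:
    """Transform equivalent to applying ``b`` first, then ``a``.

    The result is expressed about ``a``'s rotation centre.
    """
    m = a.matrix() @ b.matrix()
    theta = a.theta + b.theta
    th = math.radians(theta)
    c, s = math.cos(th), math.sin(th)
    cx, cy = a.center
    tx = m[0, 2] - (cx - (c * cx - s * cy))
    ty = m[1, 2] - (cy - (s * cx + c * cy))
    return RigidTransform2D(tx, ty, theta, a.center)


@dataclass(frozen=True)
class CouchCorrection:
    """Five-DOF clinical couch shift: translations in mm, angles in degrees.

    ``vert``/``lat``/``long`` are the couch vertical, lateral and longitudinal
    translations; ``rotation`` is the couch yaw and ``pitch`` the couch pitch.
    """

    vert: float = 0.0
    lat: float = 0.0
    long: float = 0.0
    rotation: float = 0.0
    pitch: float = 0.0

    TRANSLATION_FIELDS = ("vert", "lat", "long")
    ROTATION_FIELDS = ("rotation", "pitch")

    def __post_init__(self) -> None:
        for name in (*self.TRANSLATION_FIELDS, *self.ROTATION_FIELDS):
            if not math.isfinite(getattr(self, name)):
                raise CouchRecordError(f"couch field {name!r} must be finite")

    def __sub__(self, other: "CouchCorrection") -> "CouchCorrection":
        return CouchCorrection(
            self.vert - other.vert,
            self.lat - other.lat,
            self.long - other.long,
            self.rotation - other.rotation,
            self.pitch - other.pitch,
        )

    def to_dict(self) -> dict:
        return {
            "vert": self.vert,
            "lat": self.lat,
            "long": self.long,
            "rotation": self.rotation,
            "pitch": self.pitch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouchCorrection":
        return cls(**{k: float(d.get(k, 0.0)) for k in
                      (*cls.TRANSLATION_FIELDS, *cls.ROTATION_FIELDS)})
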