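"""Synthetic DRR/kV phantom pairs with exact ground truth.

The generator renders a head-and-shoulders scene from geometric
primitives (skull, brain, spine, shoulders, clavicles) into a clean
high-contrast "DRR" image, then produces a degraded "kV" counterpart by
re-rendering the scene under a known rigid transform and passing it
through a monotone nonlinear intensity remap (gamma), a contrast
reduction with a baseline offset, and additive Gaussian noise — the same
qualitative mismatch a flat-panel kV radiograph shows against a
planning-CT DRR, which is what makes histogram matching a genuine
prerequisite for meaningful similarity landscapes rather than a no-op.

Rendering is analytic with 4x supersampling (2x2 subpixel samples), so
the planted transform is exact: the registration transform that aligns
the moving image back onto the fixed one equals ``spec.truth``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import ConfigError, ProjectionImage, RigidTransform2D

#: Structure groups used by the articulated (skull-vs-shoulders) phantom.
SKULL_GROUP = "skull"
BODY_GROUP = "body"


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse primitive; centre and semi-axes in mm, angle in degrees."""

    center: tuple[float, float]
    axes: tuple[float, float]
    intensity: float
    angle: float = 0.0
    group: str = BODY_GROUP

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        th = math.radians(self.angle)
        c, s = math.cos(th), math.sin(th)
        dx = x - self.center[0]
        dy = y - self.center[1]
        u = (c * dx + s * dy) / self.axes[0]
        v = (-s * dx + c * dy) / self.axes[1]
        return u * u + v * v <= 1.0

    def bounds(self) -> tuple[float, float, float, float]:
        th = math.radians(self.angle)
        ex = math.hypot(self.axes[0] * math.cos(th), self.axes[1] * math.sin(th))
        ey = math.hypot(self.axes[0] * math.sin(th), self.axes[1] * math.cos(th))
        return (self.center[0] - ex, self.center[0] + ex,
                self.center[1] - ey, self.center[1] + ey)

    def moved(self, t: RigidTransform2D) -> "Ellipse":
        cx, cy = t.apply(np.array(self.center, dtype=float))
        return replace(self, center=(float(cx), float(cy)), angle=self.angle + t.theta)


@dataclass(frozen=True)
class Rectangle:
    """Filled rectangle primitive; centre and full size in mm, angle in degrees."""

    center: tuple[float, float]
    size: tuple[float, float]
    intensity: float
    angle: float = 0.0
    group: str = BODY_GROUP

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        th = math.radians(self.angle)
        c, s = math.cos(th), math.sin(th)
        dx = x - self.center[0]
        dy = y - self.center[1]
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (np.abs(u) <= self.size[0] / 2) & (np.abs(v) <= self.size[1] / 2)

    def bounds(self) -> tuple[float, float, float, float]:
        th = math.radians(self.angle)
        c, s = abs(math.cos(th)), abs(math.sin(th))
        ex = (self.size[0] * c + self.size[1] * s) / 2
        ey = (self.size[0] * s + self.size[1] * c) / 2
        return (self.center[0] - ex, self.center[0] + ex,
                self.center[1] - ey, self.center[1] + ey)

    def moved(self, t: RigidTransform2D) -> "Rectangle":
        cx, cy = t.apply(np.array(self.center, dtype=float))
        return replace(self, center=(float(cx), float(cy)), angle=self.angle + t.theta)


def head_shoulders_anatomy(field_mm: float = 256.0) -> list:
    """Head-and-shoulders primitive set, scaled to a square field of view.

    Intensities are line-integral-like: bone bright, soft tissue mid,
    background zero.  A small off-midline sinus keeps the scene free of
    left-right symmetry so rotations are identifiable.  The scene is
    deliberately aperiodic, giving a single, well-conditioned similarity
    basin — the conditions of a routine setup image.
    """
    f = field_mm / 256.0
    return [
        # torso / shoulders block
        Rectangle(center=(128 * f, 200 * f), size=(200 * f, 80 * f),
                  intensity=0.35, group=BODY_GROUP),
        # clavicles
        Rectangle(center=(78 * f, 172 * f), size=(70 * f, 10 * f), angle=8.0,
                  intensity=0.65, group=BODY_GROUP),
        Rectangle(center=(178 * f, 172 * f), size=(70 * f, 10 * f), angle=-8.0,
                  intensity=0.65, group=BODY_GROUP),
        # cervical spine
        Rectangle(center=(128 * f, 160 * f), size=(18 * f, 90 * f),
                  intensity=0.75, group=BODY_GROUP),
        # skull: outer table, brain, sinus (off-midline), jaw
        Ellipse(center=(128 * f, 82 * f), axes=(52 * f, 62 * f),
                intensity=0.85, group=SKULL_GROUP),
        Ellipse(center=(128 * f, 78 * f), axes=(40 * f, 48 * f),
                intensity=0.45, group=SKULL_GROUP),
        Ellipse(center=(112 * f, 64 * f), axes=(10 * f, 14 * f),
                intensity=0.2, group=SKULL_GROUP),
        Rectangle(center=(140 * f, 118 * f), size=(36 * f, 12 * f), angle=-12.0,
                  intensity=0.7, group=SKULL_GROUP),
    ]


# kept as the generic default-anatomy hook
default_anatomy = head_shoulders_anatomy


def cspine_anatomy(field_mm: float = 256.0) -> list:
    """Cervical-spine scene with a periodic vertebral column.

    The repeating vertebral bodies (16 mm pitch) plus low-intensity
    airway/lung features make this scene deliberately ill-conditioned for
    similarity metrics once soft-tissue contrast is compressed: shifting
    by one vertebral pitch re-aligns most of the visible bone, producing
    secondary basins.  Used for landscape diagnostics.
    """
    f = field_mm / 256.0
    prims = [
        Ellipse(center=(128 * f, 158 * f), axes=(86 * f, 96 * f),
                intensity=0.30, group=BODY_GROUP),
        Ellipse(center=(128 * f, 80 * f), axes=(52 * f, 62 * f),
                intensity=0.36, group=SKULL_GROUP),
        # lung apices and trachea: soft-contrast features the degradation crushes
        Ellipse(center=(86 * f, 194 * f), axes=(32 * f, 36 * f),
                intensity=0.12, group=BODY_GROUP),
        Ellipse(center=(170 * f, 194 * f), axes=(32 * f, 36 * f),
                intensity=0.12, group=BODY_GROUP),
        Rectangle(center=(120 * f, 150 * f), size=(10 * f, 70 * f),
                  intensity=0.18, group=BODY_GROUP),
    ]
    for k in range(8):  # vertebral bodies, pitch 16 mm
        prims.append(Rectangle(center=(128 * f, (126 + 16 * k) * f),
                               size=(20 * f, 11 * f), intensity=0.88,
                               group=BODY_GROUP))
    prims += [
        Ellipse(center=(128 * f, 80 * f), axes=(48 * f, 58 * f),
                intensity=0.80, group=SKULL_GROUP),
        Ellipse(center=(128 * f, 80 * f), axes=(44 * f, 54 * f),
                intensity=0.42, group=SKULL_GROUP),
        Ellipse(center=(112 * f, 62 * f), axes=(9 * f, 13 * f),
                intensity=0.22, group=SKULL_GROUP),
        Rectangle(center=(143 * f, 113 * f), size=(30 * f, 10 * f), angle=-14.0,
                  intensity=0.68, group=SKULL_GROUP),
        Rectangle(center=(76 * f, 180 * f), size=(62 * f, 9 * f), angle=8.0,
                  intensity=0.72, group=BODY_GROUP),
        Rectangle(center=(180 * f, 180 * f), size=(62 * f, 9 * f), angle=-8.0,
                  intensity=0.72, group=BODY_GROUP),
    ]
    return prims


@dataclass
class PhantomSpec:
    """Conditions under which one DRR/kV phantom pair is generated.

    ``truth`` is the rigid transform that, applied during registration,
    aligns the degraded moving image back onto the fixed one (rotation
    centre = image physical centre).  ``gamma``, ``contrast`` and
    ``offset`` define the monotone intensity degradation
    ``v -> contrast * clip(v, 0, None)**gamma + offset`` applied to the
    moving image before Gaussian noise of ``noise_sigma`` is added
    (intensities are on the DRR's [0, 1] scale).  ``shot_noise``
    additionally applies Poisson-like resampling with ``shot_scale``
    expected counts at unit intensity.
    """

    shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float] = (1.0, 1.0)
    primitives: list | None = None
    truth: RigidTransform2D | None = None
    gamma: float = 1.8
    contrast: float = 0.6
    offset: float = 0.05
    noise_sigma: float = 0.02
    shot_noise: bool = False
    shot_scale: float = 2000.0
    supersample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.gamma <= 0 or self.contrast <= 0:
            raise ConfigError("gamma and contrast must be positive")
        if self.primitives is None:
            self.primitives = head_shoulders_anatomy(self.shape[1] * self.spacing[1])
        self._validate_bounds()

    def _validate_bounds(self) -> None:
        width = self.shape[1] * self.spacing[1]
        height = self.shape[0] * self.spacing[0]
        for prim in self.primitives:
            x0, x1, y0, y1 = prim.bounds()
            if x0 < -0.5 * self.spacing[1] or y0 < -0.5 * self.spacing[0] \
                    or x1 > width or y1 > height:
                raise ConfigError(f"primitive out of the field of view: {prim}")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.shape[1] - 1) * self.spacing[1],
                0.5 * (self.shape[0] - 1) * self.spacing[0])

    def resolved_truth(self) -> RigidTransform2D:
        if self.truth is None:
            return RigidTransform2D.identity(self.center)
        if self.truth.center == (0.0, 0.0) and self.center != (0.0, 0.0):
            return self.truth.replace(center=self.center)
        return self.truth

    @classmethod
    def cspine(cls, **kwargs) -> "PhantomSpec":
        """Cervical-spine landscape phantom with its technique-limited
        degradation: strong gamma compression of soft tissue, halved
        contrast, and low quantum noise."""
        shape = kwargs.pop("shape", (256, 256))
        spacing = kwargs.pop("spacing", (1.0, 1.0))
        kwargs.setdefault("primitives", cspine_anatomy(shape[1] * spacing[1]))
        kwargs.setdefault("gamma", 3.5)
        kwargs.setdefault("contrast", 0.5)
        kwargs.setdefault("offset", 0.05)
        kwargs.setdefault("noise_sigma", 0.002)
        return cls(shape=shape, spacing=spacing, **kwargs)


def render_scene(
    primitives: list,
    shape: tuple[int, int],
    spacing: tuple[float, float],
    transform: RigidTransform2D | None = None,
    supersample: int = 2,
) -> np.ndarray:
    """Render primitives (optionally moved by ``transform``) with supersampling.

    Painter's order: later primitives overwrite earlier ones where they
    overlap, at subsample resolution, then subsamples are averaged.
    """
    if transform is not None:
        primitives = [p.moved(transform) for p in primitives]
    n_rows, n_cols = shape
    ss = max(1, int(supersample))
    # subpixel sample offsets, centred within each pixel
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    x = np.arange(n_cols) * spacing[1]
    y = np.arange(n_rows) * spacing[0]
    acc = np.zeros((n_rows, n_cols))
    for oy in offs:
        for ox in offs:
            X, Y = np.meshgrid(x + ox * spacing[1], y + oy * spacing[0])
            img = np.zeros_like(X)
            for prim in primitives:
                inside = prim.contains(X, Y)
                img[inside] = prim.intensity
            acc += img
    return acc / (ss * ss)


def _degrade(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    v = np.clip(clean, 0.0, None) ** spec.gamma
    v = spec.contrast * v + spec.offset
    if spec.shot_noise:
        v = rng.poisson(np.clip(v, 0.0, None) * spec.shot_scale) / spec.shot_scale
    if spec.noise_sigma > 0:
        v = v + rng.normal(0.0, spec.noise_sigma, size=v.shape)
    return v


def make_pair(
    spec: PhantomSpec,
) -> tuple[ProjectionImage, ProjectionImage, RigidTransform2D]:
    """Generate one (fixed DRR, moving kV, ground-truth transform) triple.

    The moving image shows the same scene displaced so that registering it
    onto the fixed image recovers exactly ``spec.truth``; it then receives
    the monotone intensity degradation and noise of the spec.
    """
    truth = spec.resolved_truth()
    fixed = render_scene(spec.primitives, spec.shape, spec.spacing,
                         supersample=spec.supersample)
    moving_clean = render_scene(spec.primitives, spec.shape, spec.spacing,
                                transform=truth, supersample=spec.supersample)
    rng = np.random.default_rng(spec.seed)
    moving = _degrade(moving_clean, spec, rng)
    fixed_img = ProjectionImage(fixed, spec.spacing, (0.0, 0.0), "DRR")
    moving_img = ProjectionImage(moving, spec.spacing, (0.0, 0.0), "KV")
    return fixed_img, moving_img, truth


def make_articulated_pair(
    spec: PhantomSpec,
    skull_transform: RigidTransform2D,
    body_transform: RigidTransform2D,
) -> tuple[ProjectionImage, ProjectionImage, dict[str, RigidTransform2D]]:
    """Phantom pair in which the skull and the body move differently.

    Models the clinical flexion/articulation mismatch: no single rigid
    transform aligns the pair, so independent registrations may disagree.
    Returns the component truths keyed by structure group.
    """
    def resolve(t: RigidTransform2D) -> RigidTransform2D:
        if t.center == (0.0, 0.0) and spec.center != (0.0, 0.0):
            return t.replace(center=spec.center)
        return t

    skull_t = resolve(skull_transform)
    body_t = resolve(body_transform)
    fixed = render_scene(spec.primitives, spec.shape, spec.spacing,
                         supersample=spec.supersample)
    moved = [
        p.moved(skull_t if p.group == SKULL_GROUP else body_t)
        for p in spec.primitives
    ]
    moving_clean = render_scene(moved, spec.shape, spec.spacing,
                                supersample=spec.supersample)
    rng = np.random.default_rng(spec.seed)
    moving = _degrade(moving_clean, spec, rng)
    fixed_img = ProjectionImage(fixed, spec.spacing, (0.0, 0.0), "DRR")
    moving_img = ProjectionImage(moving, spec.spacing, (0.0, 0.0), "KV")
    return fixed_img, moving_img, {SKULL_GROUP: skull_t, BODY_GROUP: body_t}


@dataclass
class Case:
    """One synthetic verification case: image pair, truth, and the
    simulated clinical correction (truth plus setup-software jitter)."""

    index: int
    fixed: ProjectionImage
    moving: ProjectionImage
    truth: RigidTransform2D
    clinical: RigidTransform2D
    articulated: bool = False


def make_case_batch(
    n: int,
    shift_mm: float = 15.0,
    rot_deg: float = 3.0,
    jitter_mm: float = 0.3,
    jitter_deg: float = 0.1,
    articulation_fraction: float = 0.0,
    articulation_deg: float = 3.0,
    n_outliers: int = 0,
    outlier_mm: float = 5.0,
    noise_sigma: float = 0.02,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[list[Case], dict]:
    """Generate a reproducible batch of verification cases.

    True shifts are uniform in ±``shift_mm`` / ±``rot_deg``; the simulated
    clinical correction is the truth plus Gaussian jitter (sigma
    ``jitter_mm`` / ``jitter_deg``).  The first ``n_outliers`` cases get an
    extra ``outlier_mm`` offset on one translation axis of the clinical
    record (planted discrepancies).  A leading fraction of cases is
    articulated: the skull additionally rotates by ``articulation_deg``
    relative to the body.  Returns the cases and a manifest describing the
    distributions used.
    """
    if n < 1:
        raise ConfigError("need at least one case")
    rng = np.random.default_rng(seed)
    n_artic = int(round(articulation_fraction * n))
    cases: list[Case] = []
    for i in range(n):
        tx, ty = rng.uniform(-shift_mm, shift_mm, size=2)
        th = rng.uniform(-rot_deg, rot_deg)
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            shape=shape,
            truth=RigidTransform2D(float(tx), float(ty), float(th)),
            noise_sigma=noise_sigma,
            seed=case_seed,
        )
        articulated = i < n_artic
        if articulated:
            body_t = spec.resolved_truth()
            skull_t = body_t.replace(theta=body_t.theta + articulation_deg)
            fixed, moving, truths = make_articulated_pair(spec, skull_t, body_t)
            truth = truths[BODY_GROUP]
        else:
            fixed, moving, truth = make_pair(spec)
        jitter = rng.normal(0.0, [jitter_mm, jitter_mm, jitter_deg])
        if i < n_outliers:
            axis = int(rng.integers(0, 2))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            jitter[axis] += sign * outlier_mm
        clinical = RigidTransform2D(
            truth.tx + float(jitter[0]),
            truth.ty + float(jitter[1]),
            truth.theta + float(jitter[2]),
            truth.center,
        )
        cases.append(Case(i, fixed, moving, truth, clinical, articulated))
    manifest = {
        "n": n,
        "shift_mm": shift_mm,
        "rot_deg": rot_deg,
        "jitter": {"translation_sigma_mm": jitter_mm, "rotation_sigma_deg": jitter_deg,
                   "distribution": "gaussian"},
        "n_outliers": n_outliers,
        "outlier_mm": outlier_mm,
        "articulation_fraction": articulation_fraction,
        "articulation_deg": articulation_deg,
        "noise_sigma": noise_sigma,
        "shape": list(shape),
        "seed": seed,
    }
    return cases, manifest
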