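"""Seeded generators for every test surface.

Real atlas data — reconstructed embryo volumes, curated mapped
expression patterns, raw assay photographs — cannot ship with the
package, so each pipeline stage has a deterministic synthetic
counterpart with known ground truth:

* phantom embryo volumes: a smooth ellipsoidal grey body with three
  nested "anatomy" domains (and a spherically symmetric variant whose
  grey level depends only on radius, for rotation-invariance checks of
  the sectioning code);
* expression-pattern sets with *planted* syn-expression groups: each
  group derives from one template domain, members differ by toggling a
  fraction of boundary-adjacent voxels (morphological jitter, the way
  biological boundaries vary), and groups are spatially disjoint so the
  planted partition is unambiguous;
* assay cases: a signal-coloured region drawn in a deformed "data"
  image together with landmarks sampled from the true deformation and
  the ground-truth mapped domain in the model frame.

All generators are pure functions of their seed/spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .intervals import Frame, IntervalDomain, from_mask
from .mapping import ColourThresholds, HSVBand, LandmarkSet
from .sectioning import CompoundObject, GreyVolume, Layer
from .similarity import ExpressionPattern

__all__ = [
    "FixtureSpec",
    "AssayCase",
    "make_phantom_volume",
    "make_expression_set",
    "make_assay_case",
    "default_thresholds",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted syn-expression fixture.

    frame_shape is ``(nz, ny, nx)``; groups are laid out along the y
    axis with template half-axes scaled to the inter-group spacing, so
    members of different groups can never touch.  ``jitter`` is the
    fraction of template voxels toggled per member (boundary-adjacent
    voxels only).
    """

    seed: int = 0
    frame_shape: tuple[int, int, int] = (80, 120, 100)
    n_groups: int = 3
    patterns_per_group: int = 5
    jitter: float = 0.1
    frame_id: str = "synthetic-TS17"
    stage: str = "TS17"

    def __post_init__(self):
        if not 0.0 <= self.jitter < 0.5:
            raise ValueError("jitter must be in [0, 0.5)")
        if self.n_groups < 1 or self.patterns_per_group < 1:
            raise ValueError("need at least one group and one pattern per group")
        spacing = self.frame_shape[1] / (self.n_groups + 1)
        if spacing < 4:
            raise ValueError("too many groups for the frame: templates would overlap")


def _ellipsoid_mask(shape, centre, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return q <= 1.0


def make_phantom_volume(
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 80, 72),
    spherical: bool = False,
    frame_id: str | None = None,
) -> tuple[GreyVolume, CompoundObject]:
    """Phantom embryo: smooth grey volume plus three nested anatomy layers.

    With ``spherical=True`` the grey value is a (seeded, smooth) function
    of the distance from the volume centre only, so any section through
    the centre has the same intensity statistics regardless of
    orientation — the oracle for sectioning rotation-invariance tests.
    """
    rng = np.random.default_rng(seed)
    frame = Frame(frame_id or f"phantom-{seed}{'-sph' if spherical else ''}", shape)
    centre = tuple((s - 1) / 2.0 for s in shape)
    zz, yy, xx = np.ogrid[tuple(slice(0, s) for s in shape)]

    if spherical:
        radius = min(shape) / 2.0 - 2.0
        r = np.sqrt(
            (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
        )
        # smooth seeded radial profile, zero beyond the phantom radius
        knots = np.linspace(0.0, radius, 8)
        prof = np.abs(rng.normal(120.0, 40.0, size=8))
        prof = ndimage.gaussian_filter1d(prof, 1.0)
        grey = np.interp(r, knots, prof, right=0.0)
        grey[r > radius] = 0.0
        radii = (radius, radius, radius)
    else:
        radii = tuple(0.45 * s for s in shape)
        q = sum(
            ((g - c) / rr) ** 2 for g, c, rr in zip((zz, yy, xx), centre, radii)
        )
        body = np.clip(1.0 - q, 0.0, None)
        noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 3.0)
        grey = 220.0 * body ** 0.7 + 12.0 * noise
        grey[q > 1.0] = 0.0
        grey = np.clip(grey, 0.0, None)

    layers = []
    for name, colour, alpha, scale in (
        ("embryo", "#3a6ea5", 0.35, 1.0),
        ("trunk", "#2e8b57", 0.5, 0.62),
        ("heart", "#b22222", 0.7, 0.3),
    ):
        mask = _ellipsoid_mask(shape, centre, tuple(r * scale for r in radii))
        layers.append(
            Layer(name=name, domain=from_mask(mask, frame), colour=colour, alpha=alpha)
        )
    return GreyVolume(grey, frame=frame), CompoundObject(layers)


def make_expression_set(
    spec: FixtureSpec,
) -> tuple[list[ExpressionPattern], dict[str, int]]:
    """Expression patterns with planted syn-expression groups.

    Returns the patterns plus the hidden ground-truth group label per
    entry id.  Each member's "detected" domain is its group template
    with ``jitter * |template|`` boundary-band voxels toggled; the
    "strong" level is the once-eroded template core (shared within a
    group, always contained in every member).  Templates of different
    groups are disjoint by construction, so between-group Jaccard is 0
    while within-group Jaccard stays near (1−2j)/(1+2j).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.frame_shape
    frame = Frame(spec.frame_id, spec.frame_shape)
    spacing = ny / (spec.n_groups + 1)

    patterns: list[ExpressionPattern] = []
    labels: dict[str, int] = {}
    idx = 0
    for g in range(spec.n_groups):
        cy = spacing * (g + 1)
        cz = nz / 2.0 + rng.uniform(-0.08, 0.08) * nz
        cx = nx / 2.0 + rng.uniform(-0.15, 0.15) * nx
        ry = spacing * 0.35 * rng.uniform(0.85, 1.0)
        rz = min(nz * 0.3, spacing * 0.6) * rng.uniform(0.8, 1.0)
        rx = min(nx * 0.3, spacing * 0.6) * rng.uniform(0.8, 1.0)
        template = _ellipsoid_mask(spec.frame_shape, (cz, cy, cx), (rz, ry, rx))
        interior = ndimage.binary_erosion(template)
        band = ndimage.binary_dilation(template) ^ interior
        band_idx = np.flatnonzero(band)
        strong = from_mask(interior, frame)
        tsize = int(template.sum())
        n_toggle = min(int(round(spec.jitter * tsize)), len(band_idx))
        for m in range(spec.patterns_per_group):
            mask = template.copy()
            if n_toggle:
                flip = rng.choice(band_idx, size=n_toggle, replace=False)
                flat = mask.reshape(-1)
                flat[flip] = ~flat[flip]
            detected = from_mask(mask, frame)
            entry_id = f"SYN:{1000 + idx}"
            patterns.append(
                ExpressionPattern(
                    entry_id=entry_id,
                    gene=f"GeneG{g + 1}{chr(ord('a') + m % 26)}",
                    stage=spec.stage,
                    levels={"detected": detected, "strong": strong},
                    frame=frame,
                )
            )
            labels[entry_id] = g
            idx += 1
    return patterns, labels


def default_thresholds() -> ColourThresholds:
    """Nested HSV bands for a purple ISH chromogen on a pale background."""
    return ColourThresholds(
        {
            "detected": HSVBand(hue=(220.0, 320.0), sat_min=0.15, val=(0.04, 0.98)),
            "weak": HSVBand(hue=(228.0, 312.0), sat_min=0.20, val=(0.06, 0.95)),
            "moderate": HSVBand(hue=(236.0, 304.0), sat_min=0.28, val=(0.08, 0.90)),
            "strong": HSVBand(hue=(244.0, 296.0), sat_min=0.40, val=(0.10, 0.80)),
        }
    )


@dataclass
class AssayCase:
    """One synthetic curation case with known ground truth.

    ``affine`` is the true data->model map as a 3x3 homogeneous matrix;
    ``truth`` is the mapped "detected" domain the pipeline should
    recover in the model frame.
    """

    image: np.ndarray
    landmarks: LandmarkSet
    truth: IntervalDomain
    thresholds: ColourThresholds = field(default_factory=default_thresholds)
    model_frame: Frame = Frame("model-2d", (160, 160))
    affine: np.ndarray = field(default_factory=lambda: np.eye(3))


def _grid_landmarks(n: int, lo: float, hi: float) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n)))
    axis = np.linspace(lo, hi, side)
    gx, gy = np.meshgrid(axis, axis)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)[:n]


def make_assay_case(
    seed: int = 0,
    n_landmarks: int = 9,
    model_shape: tuple[int, int] = (160, 160),
    deformation: str = "affine",
) -> AssayCase:
    """Signal-coloured ellipse in a deformed data image, with landmarks
    sampled from the true deformation and the exact mapped domain.

    deformation : "affine" (seeded rotation/scale/translation about the
        image centre) or "identity".
    """
    rng = np.random.default_rng(seed)
    ny, nx = model_shape
    frame = Frame("model-2d", model_shape)
    centre = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])

    if deformation == "identity":
        aff = np.eye(3)
    elif deformation == "affine":
        ang = np.deg2rad(rng.uniform(-15.0, 15.0))
        scale = rng.uniform(0.92, 1.08)
        trans = rng.uniform(-6.0, 6.0, size=2)
        rot = scale * np.array(
            [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
        )
        aff = np.eye(3)
        aff[:2, :2] = rot
        aff[:2, 2] = centre - rot @ centre + trans
    else:
        raise ValueError(f"unknown deformation {deformation!r}")

    # ground-truth ellipse in the model frame (analytic membership)
    ecx, ecy = centre + rng.uniform(-6.0, 6.0, size=2)
    a_ax = rng.uniform(38.0, 44.0)
    b_ax = rng.uniform(30.0, 36.0)
    phi = np.deg2rad(rng.uniform(0.0, 180.0))

    def in_ellipse(x, y):
        dx, dy = x - ecx, y - ecy
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        return (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0

    gy, gx = np.mgrid[0:ny, 0:nx]
    truth = from_mask(in_ellipse(gx, gy), frame)

    # data image: pixel p carries signal iff the true map sends it into
    # the ellipse; colours sit safely inside / outside the HSV bands
    mapped = aff @ np.stack([gx.ravel(), gy.ravel(), np.ones(gx.size)])
    signal = in_ellipse(mapped[0], mapped[1]).reshape(ny, nx)
    img = np.empty((ny, nx, 3), dtype=np.uint8)
    bg = np.array([235, 228, 214], dtype=np.int16)
    fg = np.array([95, 40, 135], dtype=np.int16)
    img[:] = np.clip(bg + rng.integers(-6, 7, size=(ny, nx, 3)), 0, 255).astype(np.uint8)
    noise = rng.integers(-8, 9, size=(int(signal.sum()), 3))
    img[signal] = np.clip(fg + noise, 0, 255).astype(np.uint8)

    src = _grid_landmarks(n_landmarks, 6.0, min(nx, ny) - 7.0)
    dst = (aff @ np.vstack([src.T, np.ones(len(src))]))[:2].T
    return AssayCase(
        image=img,
        landmarks=LandmarkSet(src, dst),
        truth=truth,
        thresholds=default_thresholds(),
        model_frame=frame,
        affine=aff,
    )
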