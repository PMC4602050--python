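"""Arbitrary-plane virtual sectioning of 3D volumes and domain overlays.

A section plane is parameterised the way an interactive atlas viewer
drives it: a fixed point (the rotation centre), three rotation angles —
yaw about the volume z axis, then pitch about the rotated x axis, then
roll about the resulting view normal — a signed distance along the view
normal, an isotropic zoom factor and a viewport.  The induced rigid map
takes section pixel coordinates (u, v) to continuous volume coordinates;
grey values are sampled by nearest-neighbour or trilinear interpolation,
and interval domains are cut by nearest-voxel membership so domain
sections stay binary and interval-codable.

Overlapping domains are first-class: a :class:`CompoundObject` is an
ordered list of named layers, each with its own colour and transparency,
composited back-to-front over the grey section.  Nothing here imposes
the one-label-per-voxel restriction of index images (see
:func:`emas.io.export_index_volume` for that export and its policy).

Coordinate conventions: volume arrays are indexed ``[z, y, x]``; vectors
are ``(x, y, z)`` with x = column, y = row (v axis points down, matching
image display).  Anisotropic voxel spacing is applied before rotation,
so sampling happens in physical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .intervals import Frame, IntervalDomain, from_mask, to_mask

__all__ = [
    "GreyVolume",
    "SectionSpec",
    "Layer",
    "CompoundObject",
    "SectionTransform",
    "section_transform",
    "cut_section",
    "cut_domain_section",
    "composite",
    "render_section",
    "get_tile",
    "parse_colour",
]


@dataclass
class GreyVolume:
    """3D scalar image with voxel spacing, indexed ``[z, y, x]``."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (sx, sy, sz)
    frame: Frame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.frame is None:
            self.frame = Frame("volume", self.data.shape)


@dataclass(frozen=True)
class SectionSpec:
    """Cutting-plane parameters.

    fixed_point : rotation centre, voxel coordinates (x, y, z)
    pitch, yaw, roll : degrees (any real; normalised mod 360)
    distance : signed offset along the view normal, physical units
    scale : section pixels per physical unit (zoom), > 0
    width, height : viewport size in section pixels
    origin : in-plane offset (u0, v0) added to pixel coordinates before
        scaling; (0, 0) places section pixel (0, 0) at the fixed point
        (plus the distance offset)
    """

    fixed_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0
    distance: float = 0.0
    scale: float = 1.0
    width: int = 1
    height: int = 1
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("viewport must be at least 1x1 pixels")


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


class SectionTransform:
    """Rigid map between section pixels (u, v) and volume voxel coordinates.

    Rotation convention: intrinsic yaw (about z), then pitch (about the
    rotated x axis), then roll (about the view normal) — the composed
    matrix is ``Rz(yaw) @ Rx(pitch) @ Rz(roll)``.  The plane passes
    through ``fixed_point + distance * normal``.
    """

    def __init__(self, spec: SectionSpec, spacing: Sequence[float] = (1.0, 1.0, 1.0)):
        self.spec = spec
        self.spacing = np.asarray(spacing, dtype=float)
        r = _rot_z(spec.yaw) @ _rot_x(spec.pitch) @ _rot_z(spec.roll)
        self.e_u = r[:, 0]
        self.e_v = r[:, 1]
        self.normal = r[:, 2]
        fp_phys = np.asarray(spec.fixed_point, dtype=float) * self.spacing
        self.centre = fp_phys + spec.distance * self.normal

    def forward(self, uv: np.ndarray) -> np.ndarray:
        """Map (n, 2) section pixel coords to (n, 3) voxel (x, y, z) coords."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        s = self.spec
        plane = (uv + np.asarray(s.origin)) / s.scale
        phys = (
            self.centre
            + plane[:, :1] * self.e_u
            + plane[:, 1:2] * self.e_v
        )
        return phys / self.spacing

    def inverse(self, xyz: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel coords to (n, 3) ``(u, v, w)`` where w is the
        signed out-of-plane physical offset (0 on the section plane)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        q = xyz * self.spacing - self.centre
        s = self.spec
        u = q @ self.e_u * s.scale - s.origin[0]
        v = q @ self.e_v * s.scale - s.origin[1]
        w = q @ self.normal
        return np.stack([u, v, w], axis=1)


def section_transform(
    spec: SectionSpec, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> SectionTransform:
    """Build the section pixel -> volume coordinate map for a cutting plane."""
    return SectionTransform(spec, spacing)


def _sample_coords(spec: SectionSpec, spacing) -> np.ndarray:
    """Voxel-space (z, y, x) sample coordinates for the whole viewport,
    shaped (3, height, width)."""
    tf = section_transform(spec, spacing)
    uu, vv = np.meshgrid(np.arange(spec.width), np.arange(spec.height))
    uv = np.stack([uu.ravel(), vv.ravel()], axis=1)
    xyz = tf.forward(uv)
    return xyz[:, ::-1].T.reshape(3, spec.height, spec.width)


def cut_section(
    vol: GreyVolume,
    spec: SectionSpec,
    interpolation: str = "nearest",
    background: float = 0.0,
) -> np.ndarray:
    """Resample the volume on the section plane: a (height, width) image.

    Pixels whose sample point falls outside the volume get ``background``.
    """
    order = {"nearest": 0, "trilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    coords = _sample_coords(spec, vol.spacing)
    return ndimage.map_coordinates(
        vol.data.astype(float), coords, order=order, mode="constant", cval=background
    )


def cut_domain_section(dom: IntervalDomain, spec: SectionSpec,
                       spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> IntervalDomain:
    """2D section through a 3D domain by nearest-voxel membership.

    The result is the set of section pixels whose pulled-back sample
    point rounds to a voxel inside the domain; binary, interval-coded,
    frameless (it lives in section viewport coordinates).
    """
    if dom.dim != 3:
        raise ValueError("cut_domain_section requires a 3D domain")
    out = np.zeros((spec.height, spec.width), dtype=bool)
    if not dom.is_empty:
        coords = np.rint(_sample_coords(spec, spacing)).astype(np.int64)
        if dom.frame is not None:
            shape = dom.frame.shape
        else:
            shape = tuple(hi for _, hi in dom.bbox)
        inb = np.ones(out.shape, dtype=bool)
        for axis in range(3):
            inb &= (coords[axis] >= 0) & (coords[axis] < shape[axis])
        mask = to_mask(dom, shape)
        zi, yi, xi = (coords[a][inb] for a in range(3))
        out[inb] = mask[zi, yi, xi]
    return from_mask(out)


# ----------------------------------------------------------------------
# compound objects and compositing
# ----------------------------------------------------------------------
@dataclass
class Layer:
    """One named overlay domain with display colour and transparency."""

    name: str
    domain: IntervalDomain
    colour: tuple[float, float, float] | str = (1.0, 0.0, 0.0)
    alpha: float = 1.0
    visible: bool = True

    def __post_init__(self):
        self.colour = parse_colour(self.colour)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class CompoundObject:
    """Ordered set of named, freely overlapping domains in one frame."""

    layers: list[Layer] = field(default_factory=list)

    def __post_init__(self):
        frames = {layer.domain.frame for layer in self.layers}
        if len(frames) > 1:
            raise ValueError(f"compound layers span multiple frames: {frames}")

    @property
    def frame(self) -> Frame | None:
        return self.layers[0].domain.frame if self.layers else None

    def visible_layers(self) -> list[Layer]:
        return [la for la in self.layers if la.visible]

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)


def parse_colour(colour) -> tuple[float, float, float]:
    """Accept '#RRGGBB' or an RGB triple (0..1 floats or 0..255 ints)."""
    if isinstance(colour, str):
        c = colour.lstrip("#")
        if len(c) != 6:
            raise ValueError(f"bad colour string {colour!r}")
        return tuple(int(c[i : i + 2], 16) / 255.0 for i in (0, 2, 4))  # type: ignore
    r, g, b = colour
    if max(r, g, b) > 1.0:
        return (r / 255.0, g / 255.0, b / 255.0)
    return (float(r), float(g), float(b))


def _to_unit_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    out = img.astype(float)
    mx = out.max() if out.size else 1.0
    if mx > 1.0:
        out = out / mx
    return np.clip(out, 0.0, 1.0)


def composite(grey: np.ndarray, layers: Sequence[Layer]) -> np.ndarray:
    """Source-over blend of domain layers onto a grey section image.

    Back-to-front in list order: within each layer's 2D domain,
    ``out = alpha * colour + (1 - alpha) * under``.  Returns uint8 RGB.
    """
    base = _to_unit_float(grey)
    if base.ndim != 2:
        raise ValueError("grey section must be a 2D image")
    out = np.repeat(base[:, :, None], 3, axis=2)
    for layer in layers:
        if not layer.visible:
            continue
        mask = layer.domain.to_mask(base.shape)
        col = np.asarray(layer.colour)
        out[mask] = layer.alpha * col + (1.0 - layer.alpha) * out[mask]
    return np.rint(out * 255.0).astype(np.uint8)


def render_section(
    vol: GreyVolume,
    compound: CompoundObject | None,
    spec: SectionSpec,
    interpolation: str = "nearest",
    background: float = 0.0,
) -> np.ndarray:
    """Cut the grey section, cut every visible layer, composite: uint8 RGB."""
    grey = cut_section(vol, spec, interpolation=interpolation, background=background)
    cut_layers = []
    if compound is not None:
        for layer in compound.visible_layers():
            dom2d = cut_domain_section(layer.domain, spec, vol.spacing)
            cut_layers.append(replace(layer, domain=dom2d))
    # normalise grey against the volume range so tiles share one scale
    vmax = float(vol.data.max()) if vol.data.size else 1.0
    if vmax > 1.0:
        grey = grey / vmax
    return composite(grey, cut_layers)


def get_tile(
    vol: GreyVolume,
    compound: CompoundObject | None,
    spec: SectionSpec,
    tile_index: tuple[int, int],
    tile_size: int = 256,
    interpolation: str = "nearest",
    background: float = 0.0,
) -> np.ndarray:
    """Fixed-size RGB tile (i, j) of the composited section.

    Tile (i, j) covers columns ``i*tile_size`` onward and rows
    ``j*tile_size`` onward; edge tiles are padded with the background so
    every tile is exactly ``tile_size`` square, and mosaicking all tiles
    reproduces the full section.
    """
    i, j = tile_index
    if i < 0 or j < 0:
        raise ValueError("tile indices must be non-negative")
    if i * tile_size >= spec.width or j * tile_size >= spec.height:
        raise ValueError(
            f"tile {tile_index} outside viewport {spec.width}x{spec.height}"
        )
    full = render_section(vol, compound, spec, interpolation, background)
    bg = np.rint(np.clip(background, 0.0, 1.0) * 255.0).astype(np.uint8)
    tile = np.full((tile_size, tile_size, 3), bg, dtype=np.uint8)
    sub = full[j * tile_size : (j + 1) * tile_size, i * tile_size : (i + 1) * tile_size]
    tile[: sub.shape[0], : sub.shape[1]] = sub
    return tile
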