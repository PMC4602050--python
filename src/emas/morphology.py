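"""Morphological and topological operators over interval domains.

Dilation and erosion are computed directly in interval space: the unit
structuring element (a diamond for 4/6-connectivity, a square/cube for
8/26-connectivity) is applied as a union (dilation) or intersection
(erosion) of integer translates of the domain, iterated ``radius`` times.
When the domain carries a frame, dilation is clipped to the frame at every
step, so behaviour at the reference-model boundary is reproducible.

Distance transforms and connected-component labelling are delegated to
``scipy.ndimage`` via a dense round-trip; both are standard grid
algorithms with no interval-specific semantics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .intervals import (
    Frame,
    IntervalDomain,
    clip,
    from_mask,
    intersect,
    to_mask,
    translate,
    union,
)

__all__ = [
    "StructuringSpec",
    "DistanceField",
    "dilate",
    "erode",
    "distance_transform",
    "label",
    "threshold_segment",
]

#: valid connectivities per dimension
_CONNECTIVITIES = {2: (4, 8), 3: (6, 26)}


@dataclass(frozen=True)
class StructuringSpec:
    """Radius (in voxels) and grid connectivity of a structuring element.

    Connectivity 4 (2D) / 6 (3D) gives the city-block unit diamond;
    8 / 26 gives the chessboard unit square / cube.
    """

    radius: int = 1
    connectivity: int = 8

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.connectivity not in (4, 6, 8, 26):
            raise ValueError("connectivity must be 4, 8 (2D) or 6, 26 (3D)")


@dataclass(frozen=True)
class DistanceField:
    """Integer grid distances to a source domain within a frame.

    ``values`` is 0 exactly on the source domain and the path-count
    distance (under the metric's connectivity) elsewhere.
    """

    values: np.ndarray
    metric: str
    frame: Frame | None = None


def _unit_offsets(dim: int, connectivity: int) -> list[tuple[int, ...]]:
    if connectivity not in _CONNECTIVITIES[dim]:
        raise ValueError(f"connectivity {connectivity} invalid for {dim}D")
    full = connectivity in (8, 26)
    offs = []
    for off in itertools.product((-1, 0, 1), repeat=dim):
        if full or sum(abs(o) for o in off) <= 1:
            offs.append(off)
    return offs


def _scipy_structure(dim: int, connectivity: int) -> np.ndarray:
    order = dim if connectivity in (8, 26) else 1
    return ndimage.generate_binary_structure(dim, order)


def dilate(a: IntervalDomain, s: StructuringSpec) -> IntervalDomain:
    """Morphological dilation: union of unit-element translates, iterated.

    Returns a superset of ``a``; clipped to the frame when one is present.
    """
    offsets = _unit_offsets(a.dim, s.connectivity)
    out = a
    for _ in range(s.radius):
        acc = out
        for off in offsets:
            if any(off):
                acc = union(acc, translate(out, off))
        if a.frame is not None:
            acc = clip(acc)
        out = acc
    return out


def erode(a: IntervalDomain, s: StructuringSpec) -> IntervalDomain:
    """Morphological erosion: intersection of unit-element translates,
    iterated.  Anti-extensive: always a subset of ``a``."""
    offsets = _unit_offsets(a.dim, s.connectivity)
    out = a
    for _ in range(s.radius):
        acc = out
        for off in offsets:
            if any(off):
                acc = intersect(acc, translate(out, tuple(-o for o in off)))
                if acc.is_empty:
                    return acc
        out = acc
    return out


def distance_transform(
    a: IntervalDomain,
    shape: Sequence[int] | None = None,
    metric: str = "city-block",
) -> DistanceField:
    """Integer distance from every grid point to the domain.

    metric : ``"city-block"`` (4/6-connected path counts) or
        ``"chessboard"`` (8/26-connected).
    """
    if a.is_empty:
        raise ValueError("distance transform of an empty domain is undefined")
    scipy_metric = {"city-block": "taxicab", "chessboard": "chessboard"}.get(metric)
    if scipy_metric is None:
        raise ValueError(f"unknown metric {metric!r}")
    mask = to_mask(a, shape)
    values = ndimage.distance_transform_cdt(~mask, metric=scipy_metric)
    return DistanceField(np.asarray(values), metric, a.frame)


def label(a: IntervalDomain, connectivity: int = 8) -> list[IntervalDomain]:
    """Connected components, sorted by size descending then bbox.

    The components are pairwise disjoint and their union equals ``a``.
    """
    if a.is_empty:
        return []
    if a.frame is not None:
        shape = a.frame.shape
        off = (0,) * a.dim
    else:
        box = a.bbox
        off = tuple(lo for lo, _ in box)
        shape = tuple(hi - lo for lo, hi in box)
        a = translate(a, tuple(-o for o in off))
    mask = to_mask(a, shape)
    structure = _scipy_structure(a.dim, connectivity)
    lab, n = ndimage.label(mask, structure=structure)
    comps = []
    for obj_slice, idx in zip(ndimage.find_objects(lab), range(1, n + 1)):
        sub = np.zeros(shape, dtype=bool)
        sub[obj_slice] = lab[obj_slice] == idx
        comp = from_mask(sub, a.frame)
        if any(off):
            comp = translate(comp, off)
        comps.append(comp)
    comps.sort(key=lambda d: (-d.size, d.bbox))
    return comps


def threshold_segment(
    image: np.ndarray,
    low: float,
    high: float,
    frame: Frame | None = None,
) -> IntervalDomain:
    """Domain of grid points with ``low <= value <= high``."""
    if low > high:
        raise ValueError(f"low ({low}) exceeds high ({high})")
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError("image must be a 2D or 3D scalar array")
    return from_mask((image >= low) & (image <= high), frame)
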