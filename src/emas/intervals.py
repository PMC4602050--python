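"""Interval-coded binary spatial domains and their set algebra.

A binary region of a 2D or 3D grid is stored as a run-length ("interval")
code: for every occupied row, an ordered list of maximal half-open column
intervals ``[start, end)``.  Set operations (union, intersection,
difference) then run per interval rather than per pixel, so their cost
scales with the boundary complexity of the region — on average one
dimension lower than the area or volume of the grid.  This representation
is the universal currency of the package: anatomy domains, mapped gene
expression patterns, query regions and section masks are all
:class:`IntervalDomain` objects.

Conventions
-----------
* Coordinates are 0-based; intervals are half-open ``[start, end)``.
* Grid shapes and dense masks follow numpy (row-major) axis order:
  ``(ny, nx)`` in 2D and ``(nz, ny, nx)`` in 3D.
* Canonical form: intervals within a row are sorted and *maximal* — a
  strict gap separates consecutive intervals — and empty rows/planes are
  never stored.  Two domains with the same voxel set therefore compare
  structurally equal.
* A domain may carry a :class:`Frame` (reference-model identifier plus
  grid shape).  Set operations between domains in different frames are
  an error, never a silent resample: spatial comparison is only
  meaningful within a single reference model's coordinate space.
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Frame",
    "FrameMismatchError",
    "IntervalDomain",
    "from_mask",
    "to_mask",
    "union",
    "intersect",
    "difference",
    "size",
    "intersection_size",
    "is_subset",
    "translate",
    "clip",
]


class Frame(NamedTuple):
    """Reference frame: a model identifier and its grid shape.

    ``shape`` is in array order — ``(ny, nx)`` for 2D frames,
    ``(nz, ny, nx)`` for 3D frames.
    """

    id: str
    shape: tuple[int, ...]


class FrameMismatchError(ValueError):
    """Raised when an operation mixes domains from different frames."""


def _check_frames(a: "IntervalDomain", b: "IntervalDomain") -> Frame | None:
    if a.frame != b.frame:
        raise FrameMismatchError(
            f"domains live in different frames: {a.frame!r} vs {b.frame!r}"
        )
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
    return a.frame


def _canonical_row(intervals: Sequence[Sequence[int]]) -> list[tuple[int, int]]:
    """Sort, validate and merge touching/overlapping intervals of one row."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _validate_canonical_row(arr: np.ndarray) -> None:
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("interval array must have shape (k, 2)")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("interval with start >= end")
    if arr.shape[0] > 1 and np.any(arr[1:, 0] <= arr[:-1, 1]):
        raise ValueError("intervals overlap, touch, or are unsorted")


class IntervalDomain:
    """Canonical interval-coded binary region of a 2D or 3D grid.

    Internally a mapping ``plane index -> row index -> (k, 2) int array``
    of half-open column intervals.  2D domains use the single implicit
    plane ``0``.  Instances are treated as immutable; all operations
    return new domains.
    """

    __slots__ = ("dim", "frame", "_planes", "_size", "_bbox")

    def __init__(
        self,
        dim: int,
        planes: dict[int, dict[int, np.ndarray]],
        frame: Frame | None = None,
        *,
        _validated: bool = False,
    ):
        if dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if dim == 2 and set(planes) - {0}:
            raise ValueError("a 2D domain has exactly one implicit plane (index 0)")
        if not _validated:
            planes = {
                z: {
                    y: np.asarray(
                        _canonical_row(np.asarray(rows, dtype=np.int64).reshape(-1, 2)),
                        dtype=np.int64,
                    ).reshape(-1, 2)
                    for y, rows in sorted(rows_by_y.items())
                    if len(rows)
                }
                for z, rows_by_y in sorted(planes.items())
            }
            planes = {z: r for z, r in planes.items() if r}
        self.dim = dim
        self.frame = frame
        self._planes = planes
        self._size: int | None = None
        self._bbox: tuple[tuple[int, int], ...] | None | bool = False

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def empty(cls, dim: int = 2, frame: Frame | None = None) -> "IntervalDomain":
        return cls(dim, {}, frame, _validated=True)

    @classmethod
    def from_runs(
        cls,
        runs: Iterable[tuple[int, int, int, int]],
        dim: int = 3,
        frame: Frame | None = None,
    ) -> "IntervalDomain":
        """Build from ``(z, y, start, end)`` tuples (2D callers pass z=0)."""
        planes: dict[int, dict[int, list]] = {}
        for z, y, s, e in runs:
            planes.setdefault(int(z), {}).setdefault(int(y), []).append((s, e))
        return cls(dim, planes, frame)  # type: ignore[arg-type]

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return not self._planes

    @property
    def size(self) -> int:
        """Pixel/voxel count: sum of (end - start) over all intervals."""
        if self._size is None:
            self._size = int(
                sum(
                    int((arr[:, 1] - arr[:, 0]).sum())
                    for rows in self._planes.values()
                    for arr in rows.values()
                )
            )
        return self._size

    @property
    def interval_count(self) -> int:
        return sum(len(arr) for rows in self._planes.values() for arr in rows.values())

    @property
    def bbox(self) -> tuple[tuple[int, int], ...] | None:
        """Tight bounding box, one ``(min, max_exclusive)`` pair per axis in
        array order; ``None`` for the empty domain."""
        if self._bbox is False:
            if not self._planes:
                self._bbox = None
            else:
                zs = list(self._planes)
                ys = [y for rows in self._planes.values() for y in rows]
                xmin = min(
                    int(arr[0, 0]) for rows in self._planes.values() for arr in rows.values()
                )
                xmax = max(
                    int(arr[-1, 1]) for rows in self._planes.values() for arr in rows.values()
                )
                box = ((min(ys), max(ys) + 1), (xmin, xmax))
                if self.dim == 3:
                    box = ((min(zs), max(zs) + 1),) + box
                self._bbox = box
        return self._bbox  # type: ignore[return-value]

    def iter_runs(self) -> Iterator[tuple[int, int, int, int]]:
        """Yield ``(z, y, start, end)`` for every interval (z=0 in 2D)."""
        for z, rows in self._planes.items():
            for y, arr in rows.items():
                for s, e in arr:
                    yield z, y, int(s), int(e)

    def contains_point(self, point: Sequence[int]) -> bool:
        """Membership test for one grid point in array order (``(y, x)`` or
        ``(z, y, x)``)."""
        if self.dim == 2:
            z, (y, x) = 0, (int(point[0]), int(point[1]))
        else:
            z, y, x = (int(c) for c in point)
        rows = self._planes.get(z)
        if rows is None:
            return False
        arr = rows.get(y)
        if arr is None:
            return False
        i = int(np.searchsorted(arr[:, 0], x, side="right")) - 1
        return i >= 0 and x < arr[i, 1]

    def validate_canonical(self) -> None:
        """Assert the canonical-form invariants; raises ValueError on breach."""
        for z, rows in self._planes.items():
            if not rows:
                raise ValueError(f"empty plane {z} stored")
            for y, arr in rows.items():
                _validate_canonical_row(np.asarray(arr))

    # ------------------------------------------------------------------
    # equality / representation
    # ------------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalDomain):
            return NotImplemented
        if self.dim != other.dim or self.frame != other.frame:
            return False
        if self._planes.keys() != other._planes.keys():
            return False
        for z, rows in self._planes.items():
            orows = other._planes[z]
            if rows.keys() != orows.keys():
                return False
            for y, arr in rows.items():
                if not np.array_equal(arr, orows[y]):
                    return False
        return True

    def __hash__(self):  # pragma: no cover - domains are not dict keys
        raise TypeError("IntervalDomain is unhashable")

    def __repr__(self) -> str:
        return (
            f"IntervalDomain(dim={self.dim}, size={self.size}, "
            f"intervals={self.interval_count}, frame={self.frame!r})"
        )

    # operator sugar
    def __or__(self, other: "IntervalDomain") -> "IntervalDomain":
        return union(self, other)

    def __and__(self, other: "IntervalDomain") -> "IntervalDomain":
        return intersect(self, other)

    def __sub__(self, other: "IntervalDomain") -> "IntervalDomain":
        return difference(self, other)

    def to_mask(self, shape: Sequence[int] | None = None) -> np.ndarray:
        return to_mask(self, shape)


# ----------------------------------------------------------------------
# dense <-> interval conversion
# ----------------------------------------------------------------------
def from_mask(mask: np.ndarray, frame: Frame | None = None) -> IntervalDomain:
    """Interval-code a dense boolean mask (2D or 3D, array axis order).

    The input must be boolean; grey images are rejected so that an
    accidental threshold is never applied silently.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise TypeError(f"mask must be boolean, got dtype {mask.dtype}")
    if mask.ndim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    dim = mask.ndim
    m3 = mask[None] if dim == 2 else mask
    # Run starts/ends along the fastest axis, all rows at once.
    d = np.diff(m3.astype(np.int8), axis=-1, prepend=0, append=0)
    sz, sy, sx = np.nonzero(d == 1)
    _, _, ex = np.nonzero(d == -1)
    planes: dict[int, dict[int, np.ndarray]] = {}
    # Runs come out in row-major order: group consecutive (z, y) blocks.
    n = len(sx)
    i = 0
    while i < n:
        z, y = int(sz[i]), int(sy[i])
        j = i
        while j < n and sz[j] == z and sy[j] == y:
            j += 1
        arr = np.stack([sx[i:j], ex[i:j]], axis=1).astype(np.int64)
        planes.setdefault(z, {})[y] = arr
        i = j
    return IntervalDomain(dim, planes, frame, _validated=True)


def to_mask(domain: IntervalDomain, shape: Sequence[int] | None = None) -> np.ndarray:
    """Expand to a dense boolean array of the given (or frame) shape.

    The domain's bounding box must fit inside ``shape``.
    """
    if shape is None:
        if domain.frame is None:
            raise ValueError("shape required for a frameless domain")
        shape = domain.frame.shape
    shape = tuple(int(s) for s in shape)
    if len(shape) != domain.dim:
        raise ValueError(f"shape {shape} does not match domain dim {domain.dim}")
    box = domain.bbox
    if box is not None:
        for (lo, hi), extent in zip(box, shape):
            if lo < 0 or hi > extent:
                raise ValueError(f"domain bbox {box} exceeds shape {shape}")
    out = np.zeros(shape, dtype=bool)
    view = out[None] if domain.dim == 2 else out
    for z, y, s, e in domain.iter_runs():
        view[z, y, s:e] = True
    return out


# ----------------------------------------------------------------------
# per-row merge kernels
# ----------------------------------------------------------------------
def _row_union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[list[int]] = []
    i = j = 0
    na, nb = len(a), len(b)
    while i < na or j < nb:
        if j >= nb or (i < na and a[i, 0] <= b[j, 0]):
            s, e = int(a[i, 0]), int(a[i, 1])
            i += 1
        else:
            s, e = int(b[j, 0]), int(b[j, 1])
            j += 1
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1][1] = e
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _row_intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(int(a[i, 0]), int(b[j, 0]))
        e = min(int(a[i, 1]), int(b[j, 1]))
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _row_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        s, e = int(s), int(e)
        while j < len(b) and b[j, 1] <= s:
            j += 1
        k = j
        cur = s
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, int(b[k, 0])))
            cur = max(cur, int(b[k, 1]))
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


# ----------------------------------------------------------------------
# set algebra
# ----------------------------------------------------------------------
def union(a: IntervalDomain, b: IntervalDomain) -> IntervalDomain:
    """A ∪ B, canonical; cost proportional to interval count, not area."""
    frame = _check_frames(a, b)
    planes: dict[int, dict[int, np.ndarray]] = {}
    for z in sorted(a._planes.keys() | b._planes.keys()):
        ra, rb = a._planes.get(z, {}), b._planes.get(z, {})
        rows: dict[int, np.ndarray] = {}
        for y in sorted(ra.keys() | rb.keys()):
            if y not in ra:
                rows[y] = rb[y].copy()
            elif y not in rb:
                rows[y] = ra[y].copy()
            else:
                rows[y] = _row_union(ra[y], rb[y])
        planes[z] = rows
    return IntervalDomain(a.dim, planes, frame, _validated=True)


def intersect(a: IntervalDomain, b: IntervalDomain) -> IntervalDomain:
    """A ∩ B, canonical."""
    frame = _check_frames(a, b)
    planes: dict[int, dict[int, np.ndarray]] = {}
    for z in sorted(a._planes.keys() & b._planes.keys()):
        ra, rb = a._planes[z], b._planes[z]
        rows: dict[int, np.ndarray] = {}
        for y in sorted(ra.keys() & rb.keys()):
            arr = _row_intersect(ra[y], rb[y])
            if len(arr):
                rows[y] = arr
        if rows:
            planes[z] = rows
    return IntervalDomain(a.dim, planes, frame, _validated=True)


def difference(a: IntervalDomain, b: IntervalDomain) -> IntervalDomain:
    """A ∖ B, canonical."""
    frame = _check_frames(a, b)
    planes: dict[int, dict[int, np.ndarray]] = {}
    for z, ra in a._planes.items():
        rb = b._planes.get(z, {})
        rows: dict[int, np.ndarray] = {}
        for y, arr in ra.items():
            if y not in rb:
                rows[y] = arr.copy()
            else:
                res = _row_difference(arr, rb[y])
                if len(res):
                    rows[y] = res
        if rows:
            planes[z] = rows
    return IntervalDomain(a.dim, planes, frame, _validated=True)


def size(a: IntervalDomain) -> int:
    """Pixel/voxel count of the domain."""
    return a.size


def intersection_size(a: IntervalDomain, b: IntervalDomain) -> int:
    """``|A ∩ B|`` without materialising the intersection domain.

    This is the hot inner loop of Jaccard ranking over large pattern sets,
    so it walks only the rows the two domains share.
    """
    _check_frames(a, b)
    total = 0
    for z in a._planes.keys() & b._planes.keys():
        ra, rb = a._planes[z], b._planes[z]
        for y in ra.keys() & rb.keys():
            xa, xb = ra[y], rb[y]
            if len(xa) == 1 and len(xb) == 1:
                total += max(
                    0,
                    min(int(xa[0, 1]), int(xb[0, 1])) - max(int(xa[0, 0]), int(xb[0, 0])),
                )
            else:
                arr = _row_intersect(xa, xb)
                if len(arr):
                    total += int((arr[:, 1] - arr[:, 0]).sum())
    return total


def is_subset(a: IntervalDomain, b: IntervalDomain) -> bool:
    """True iff A ⊆ B (voxel-set inclusion)."""
    return intersection_size(a, b) == a.size


# ----------------------------------------------------------------------
# geometric helpers used by morphology and fixtures
# ----------------------------------------------------------------------
def translate(a: IntervalDomain, offset: Sequence[int]) -> IntervalDomain:
    """Shift by an integer offset in array order (``(dy, dx)`` or
    ``(dz, dy, dx)``).  The frame, if any, is kept; callers that may shift
    content outside the frame should :func:`clip` afterwards."""
    if a.dim == 2:
        dz, (dy, dx) = 0, (int(offset[0]), int(offset[1]))
    else:
        dz, dy, dx = (int(c) for c in offset)
    planes = {
        z + dz: {
            y + dy: (arr + dx if dx else arr.copy()) for y, arr in rows.items()
        }
        for z, rows in a._planes.items()
    }
    return IntervalDomain(a.dim, planes, a.frame, _validated=True)


def clip(a: IntervalDomain, shape: Sequence[int] | None = None) -> IntervalDomain:
    """Intersect with the rectangular region ``[0, shape)`` per axis."""
    if shape is None:
        if a.frame is None:
            return a
        shape = a.frame.shape
    shape = tuple(int(s) for s in shape)
    if a.dim == 2:
        zlim, (ylim, xlim) = 1, shape
    else:
        zlim, ylim, xlim = shape
    planes: dict[int, dict[int, np.ndarray]] = {}
    for z, rows_in in a._planes.items():
        if not (0 <= z < zlim):
            continue
        rows: dict[int, np.ndarray] = {}
        for y, arr in rows_in.items():
            if not (0 <= y < ylim):
                continue
            cl = np.clip(arr, 0, xlim)
            cl = cl[cl[:, 0] < cl[:, 1]]
            if len(cl):
                rows[y] = cl
        if rows:
            planes[z] = rows
    return IntervalDomain(a.dim, planes, a.frame, _validated=True)
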