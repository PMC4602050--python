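"""Landmark-based 2D expression mapping: warp + colour-threshold extraction.

A raw assay image (typically whole-mount in situ hybridisation) is
registered onto a stage-matched reference model through pairs of
morphologically equivalent landmark points placed on both images.  The
landmarks induce a piecewise-affine warp (Delaunay triangulation of the
source points, one affine map per triangle) that interpolates every
landmark pair exactly and is continuous across triangle edges.  Signal
is extracted from the raw image at several expression-strength levels by
colour thresholding in HSV space — the ISH chromogen (e.g. BCIP/NBT
purple) occupies a hue/saturation/value band, and stronger signal is a
stricter sub-band — then each level's domain is carried through the warp
into the model frame, yielding a mapped :class:`ExpressionPattern`.

The warp here is deliberately isolated behind :class:`WarpMesh` so a
different registration model (e.g. a constrained distance transform)
can be slotted in without touching extraction or rasterisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from skimage.color import rgb2hsv
from skimage.transform import PiecewiseAffineTransform

from .intervals import Frame, IntervalDomain, difference, from_mask, to_mask
from .similarity import LEVELS, ExpressionPattern

__all__ = [
    "LandmarkSet",
    "WarpMesh",
    "HSVBand",
    "ColourThresholds",
    "extract_signal",
    "build_warp",
    "apply_warp",
    "map_entry",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# landmarks
# ----------------------------------------------------------------------
@dataclass
class LandmarkSet:
    """Paired (source, target) 2D points in pixel units, x = column,
    origin top-left.  At least 3 non-collinear pairs define a warp."""

    source: np.ndarray  # (n, 2) float, (x, y)
    target: np.ndarray  # (n, 2) float

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 2)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 2)
        if len(self.source) != len(self.target):
            raise ValueError("source and target landmark counts differ")
        if len(self.source) < 3:
            raise ValueError("at least 3 landmark pairs are required")
        if len(np.unique(self.source, axis=0)) != len(self.source):
            raise ValueError("duplicate source landmarks")
        centred = self.source - self.source.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9) < 2:
            raise ValueError("source landmarks are collinear")

    def __len__(self):
        return len(self.source)

    @classmethod
    def from_tsv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path, sep="\t")
        missing = {"sx", "sy", "tx", "ty"} - set(df.columns)
        if missing:
            raise ValueError(f"landmark TSV missing columns: {sorted(missing)}")
        return cls(df[["sx", "sy"]].to_numpy(), df[["tx", "ty"]].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            np.hstack([self.source, self.target]), columns=["sx", "sy", "tx", "ty"]
        ).to_csv(path, sep="\t", index=False)


class WarpMesh:
    """Piecewise-affine warp from a landmark set.

    Forward: Delaunay triangulation of the source points, the affine map
    of each triangle determined by its three landmark pairs.  The
    inverse direction triangulates the target points the same way.
    Points outside the respective convex hull have no defined image and
    are returned as NaN.
    """

    def __init__(self, landmarks: LandmarkSet):
        self.landmarks = landmarks
        if hasattr(PiecewiseAffineTransform, "from_estimate"):
            tform = PiecewiseAffineTransform.from_estimate(
                landmarks.source, landmarks.target
            )
            if not tform:
                raise ValueError("failed to estimate piecewise-affine warp")
            self._tform = tform
        else:  # scikit-image < 0.26
            self._tform = PiecewiseAffineTransform()
            if not self._tform.estimate(landmarks.source, landmarks.target):
                raise ValueError("failed to estimate piecewise-affine warp")
        try:
            self._src_tri = Delaunay(landmarks.source)
            self._dst_tri = Delaunay(landmarks.target)
        except QhullError as exc:  # pragma: no cover - guarded by LandmarkSet
            raise ValueError(f"degenerate landmark configuration: {exc}") from exc

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) source (x, y) points; NaN outside the source hull."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.asarray(self._tform(points), dtype=float)
        out[self._src_tri.find_simplex(points) < 0] = np.nan
        return out

    def inverse(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) target points back; NaN outside the target hull."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.asarray(self._tform.inverse(points), dtype=float)
        out[self._dst_tri.find_simplex(points) < 0] = np.nan
        return out


def build_warp(landmarks: LandmarkSet) -> WarpMesh:
    """Piecewise-affine warp interpolating every landmark pair exactly."""
    return WarpMesh(landmarks)


# ----------------------------------------------------------------------
# colour thresholding
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class HSVBand:
    """An HSV acceptance band: hue arc (degrees, may wrap through 0),
    minimum saturation, and value (brightness) range, all in [0, 1]
    except hue in [0, 360)."""

    hue: tuple[float, float]
    sat_min: float = 0.0
    val: tuple[float, float] = (0.0, 1.0)

    def _hue_arcs(self) -> list[tuple[float, float]]:
        lo, hi = self.hue[0] % 360.0, self.hue[1] % 360.0
        if lo <= hi:
            return [(lo, hi)]
        return [(lo, 360.0), (0.0, hi)]

    def match(self, h_deg: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        hmask = np.zeros(h_deg.shape, dtype=bool)
        for lo, hi in self._hue_arcs():
            hmask |= (h_deg >= lo) & (h_deg <= hi)
        return hmask & (s >= self.sat_min) & (v >= self.val[0]) & (v <= self.val[1])

    def contains_band(self, inner: "HSVBand") -> bool:
        """True if every pixel matching ``inner`` also matches self."""
        if inner.sat_min < self.sat_min:
            return False
        if inner.val[0] < self.val[0] or inner.val[1] > self.val[1]:
            return False
        outer = self._hue_arcs()
        # merge arcs touching across 0/360
        if len(outer) == 2 and outer[0][1] >= 360.0 and outer[1][0] <= 0.0:
            merged = [(outer[0][0] - 360.0, outer[1][1]), outer[0], (outer[1][0] + 360.0, outer[1][1] + 360.0)]
            outer = merged
        for ilo, ihi in inner._hue_arcs():
            if not any(olo <= ilo and ihi <= ohi for olo, ohi in outer):
                return False
        return True


@dataclass
class ColourThresholds:
    """Per-strength-level HSV bands, nested strictest to laxest.

    Levels follow the vocabulary strong ⊂ moderate ⊂ weak ⊂ detected
    ("detected" is everything annotated as expressing).  Nesting of the
    bands is validated at construction, which guarantees that extracted
    domains nest without any post-hoc fixing.
    """

    bands: dict[str, HSVBand]

    def __post_init__(self):
        unknown = set(self.bands) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown levels: {sorted(unknown)}")
        if "detected" not in self.bands:
            raise ValueError("a 'detected' band is required")
        present = [lv for lv in LEVELS if lv in self.bands]  # strict -> lax
        for stricter, laxer in zip(present, present[1:]):
            if not self.bands[laxer].contains_band(self.bands[stricter]):
                raise ValueError(
                    f"threshold nesting violated: {stricter!r} not within {laxer!r}"
                )

    @classmethod
    def from_json(cls, path) -> "ColourThresholds":
        raw = json.loads(Path(path).read_text())
        bands = {
            lv: HSVBand(
                hue=tuple(spec["hue"]),
                sat_min=float(spec.get("sat_min", 0.0)),
                val=tuple(spec.get("val", (0.0, 1.0))),
            )
            for lv, spec in raw.items()
        }
        return cls(bands)

    def to_json(self, path) -> None:
        raw = {
            lv: {"hue": list(b.hue), "sat_min": b.sat_min, "val": list(b.val)}
            for lv, b in self.bands.items()
        }
        Path(path).write_text(json.dumps(raw, indent=2, sort_keys=True))


def extract_signal(
    image: np.ndarray,
    thresholds: ColourThresholds,
    frame: Frame | None = None,
    exclusion: IntervalDomain | None = None,
) -> dict[str, IntervalDomain]:
    """Colour-threshold an RGB image into per-level signal domains.

    Returns one interval domain per configured level; band nesting
    guarantees strong ⊆ moderate ⊆ weak ⊆ detected.  An optional
    ``exclusion`` domain (e.g. a manually outlined trapping artefact —
    chromogen pooled in a cavity without true expression) is subtracted
    from every level.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    hsv = rgb2hsv(image)
    h_deg = hsv[:, :, 0] * 360.0
    s, v = hsv[:, :, 1], hsv[:, :, 2]
    out: dict[str, IntervalDomain] = {}
    for lv, band in thresholds.bands.items():
        dom = from_mask(band.match(h_deg, s, v), frame)
        if exclusion is not None:
            dom = difference(dom, exclusion)
        out[lv] = dom
    return out


# ----------------------------------------------------------------------
# warped rasterisation
# ----------------------------------------------------------------------
def apply_warp(
    domain: IntervalDomain,
    warp: WarpMesh,
    target_frame: Frame,
) -> IntervalDomain:
    """Carry a 2D source domain through the warp into the target frame.

    Rasterisation is by inverse mapping: every target pixel centre is
    pulled back to source coordinates and tested for (nearest-pixel)
    membership in the source domain, which avoids holes.  Parts of the
    domain outside the warp's source hull are dropped with a warning; a
    nonempty in-hull domain that maps to nothing is an error.
    """
    if domain.dim != 2:
        raise ValueError("apply_warp operates on 2D domains")
    ny, nx = target_frame.shape
    out = np.zeros((ny, nx), dtype=bool)
    if domain.is_empty:
        return from_mask(out, target_frame)

    box = domain.bbox
    src_shape = (box[0][1], box[1][1])
    src_mask = to_mask(domain, src_shape)

    # in-hull part of the source domain, for diagnostics
    ys, xs = np.nonzero(src_mask)
    src_pts = np.stack([xs, ys], axis=1).astype(float)
    inside = warp._src_tri.find_simplex(src_pts) >= 0
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning(
            "%d of %d source pixels fall outside the warp mesh and are dropped",
            n_outside,
            len(src_pts),
        )

    # restrict target scan to the forward image of the in-hull pixels
    if inside.any():
        fwd = warp.forward(src_pts[inside])
        x0 = max(0, int(np.floor(fwd[:, 0].min())) - 1)
        x1 = min(nx, int(np.ceil(fwd[:, 0].max())) + 2)
        y0 = max(0, int(np.floor(fwd[:, 1].min())) - 1)
        y1 = min(ny, int(np.ceil(fwd[:, 1].max())) + 2)
    else:
        return from_mask(out, target_frame)

    tx, ty = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    tgt_pts = np.stack([tx.ravel(), ty.ravel()], axis=1).astype(float)
    back = warp.inverse(tgt_pts)
    ok = ~np.isnan(back[:, 0])
    bx = np.rint(back[ok, 0]).astype(np.int64)
    by = np.rint(back[ok, 1]).astype(np.int64)
    valid = (bx >= 0) & (bx < src_shape[1]) & (by >= 0) & (by < src_shape[0])
    member = np.zeros(len(tgt_pts), dtype=bool)
    ok_idx = np.nonzero(ok)[0][valid]
    member[ok_idx] = src_mask[by[valid], bx[valid]]
    out[ty.ravel()[member], tx.ravel()[member]] = True

    if not out.any():
        raise ValueError("warped domain is empty although source pixels lie in the mesh")
    return from_mask(out, target_frame)


def map_entry(
    image: np.ndarray,
    landmarks: LandmarkSet,
    thresholds: ColourThresholds,
    model_frame: Frame,
    entry_id: str = "entry",
    gene: str = "unknown",
    stage: str = "unknown",
    exclusion: IntervalDomain | None = None,
) -> ExpressionPattern:
    """Full curation step: extract signal, warp every level into the
    model frame, return the mapped expression pattern.

    Level nesting is preserved exactly by the shared inverse-mapping
    rasterisation: if a pixel's pulled-back point lies in a stricter
    level it also lies in every laxer one.
    """
    levels_src = extract_signal(image, thresholds, frame=None, exclusion=exclusion)
    warp = build_warp(landmarks)
    levels_dst: dict[str, IntervalDomain] = {}
    for lv, dom in levels_src.items():
        if dom.is_empty:
            levels_dst[lv] = IntervalDomain.empty(2, model_frame)
        else:
            levels_dst[lv] = apply_warp(dom, warp, model_frame)
    return ExpressionPattern(
        entry_id=entry_id, gene=gene, stage=stage, levels=levels_dst, frame=model_frame
    )
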