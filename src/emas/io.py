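"""Readers and writers for exchanged artifacts.

* ``.ivd`` / ``.ivdz`` — the package's own interval-domain serialization:
  a JSON document with half-open, 0-based intervals (gzip-wrapped for
  ``.ivdz``).  The writer is byte-stable (sorted keys, fixed formatting);
  the reader *validates* canonical form and rejects non-canonical input
  rather than silently fixing it.
* NIfTI — the sole dense 3D exchange format, via nibabel; grey volumes
  and label ("index") volumes round-trip with voxel spacing preserved.
  In-memory arrays are ``[z, y, x]``; on disk NIfTI stores x fastest.
* PNG/TIFF — 2D masks and rendered images via imageio.
* Pattern manifests — TSV tables (entry_id, gene, stage, level, path)
  referencing one ``.ivd`` file per level.

An *index image* encodes one region id per voxel and therefore cannot
represent overlapping domains; :func:`export_index_volume` makes that
restriction an explicit, testable policy instead of silent data loss.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .clustering import OccupancyMap
from .intervals import Frame, IntervalDomain, from_mask, to_mask
from .sectioning import CompoundObject, GreyVolume, Layer, parse_colour
from .similarity import ExpressionPattern

__all__ = [
    "DomainFormatError",
    "CanonicalityError",
    "BboxMismatchError",
    "IndexOverlapError",
    "read_domain",
    "write_domain",
    "read_volume",
    "write_volume",
    "read_mask_image",
    "write_mask_image",
    "export_index_volume",
    "render_heatmap",
    "FIG_PALETTE",
    "write_manifest",
    "load_manifest",
    "read_compound_json",
]

IVD_VERSION = 1

#: occupancy-class display palette: zero occupancy blue, single green,
#: dual yellow, three-plus red
FIG_PALETTE = {
    0: (0, 0, 255),
    1: (0, 255, 0),
    2: (255, 255, 0),
    3: (255, 0, 0),
}


class DomainFormatError(ValueError):
    """Malformed .ivd document (bad JSON or schema)."""


class CanonicalityError(DomainFormatError):
    """Interval lists in the file violate canonical form."""


class BboxMismatchError(DomainFormatError):
    """Stored bounding box disagrees with the intervals."""


class IndexOverlapError(ValueError):
    """Overlapping layers under the error policy of index-volume export."""


# ----------------------------------------------------------------------
# .ivd interval-domain files
# ----------------------------------------------------------------------
def domain_to_dict(domain: IntervalDomain) -> dict:
    planes = []
    grouped: dict[int, list] = {}
    for z, y, s, e in domain.iter_runs():
        grouped.setdefault(z, []).append((y, s, e))
    for z in sorted(grouped):
        rows: dict[int, list] = {}
        for y, s, e in grouped[z]:
            rows.setdefault(y, []).append([s, e])
        planes.append(
            {"z": z, "rows": [{"y": y, "intervals": rows[y]} for y in sorted(rows)]}
        )
    box = domain.bbox
    return {
        "version": IVD_VERSION,
        "dim": domain.dim,
        "frame": None
        if domain.frame is None
        else {"id": domain.frame.id, "shape": list(domain.frame.shape)},
        "bbox": None if box is None else [list(pair) for pair in box],
        "planes": planes,
    }


def domain_from_dict(doc: dict) -> IntervalDomain:
    try:
        dim = int(doc["dim"])
        planes_doc = doc["planes"]
    except (KeyError, TypeError) as exc:
        raise DomainFormatError(f"missing required field: {exc}") from exc
    frame = None
    if doc.get("frame") is not None:
        frame = Frame(str(doc["frame"]["id"]), tuple(int(s) for s in doc["frame"]["shape"]))
    planes: dict[int, dict[int, np.ndarray]] = {}
    for pl in planes_doc:
        z = int(pl["z"])
        if z in planes:
            raise DomainFormatError(f"duplicate plane {z}")
        rows: dict[int, np.ndarray] = {}
        for row in pl["rows"]:
            y = int(row["y"])
            if y in rows:
                raise DomainFormatError(f"duplicate row {y} in plane {z}")
            arr = np.asarray(row["intervals"], dtype=np.int64).reshape(-1, 2)
            if len(arr) == 0:
                raise CanonicalityError(f"empty row {y} in plane {z}")
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise CanonicalityError(f"inverted/empty interval in row {y}")
            if len(arr) > 1 and np.any(arr[1:, 0] <= arr[:-1, 1]):
                raise CanonicalityError(
                    f"overlapping, adjacent or unsorted intervals in row {y} of plane {z}"
                )
            rows[y] = arr
        if not rows:
            raise CanonicalityError(f"empty plane {z}")
        planes[z] = rows
    dom = IntervalDomain(dim, planes, frame, _validated=True)
    if doc.get("bbox") is not None:
        stored = tuple(tuple(int(v) for v in pair) for pair in doc["bbox"])
        if dom.bbox != stored:
            raise BboxMismatchError(f"stored bbox {stored} != computed {dom.bbox}")
    return dom


def write_domain(domain: IntervalDomain, path) -> None:
    """Serialize to ``.ivd`` (JSON) or ``.ivdz`` (gzip JSON); byte-stable."""
    path = Path(path)
    payload = json.dumps(
        domain_to_dict(domain), sort_keys=True, separators=(",", ":")
    ).encode()
    if path.suffix == ".ivdz":
        # mtime pinned so identical domains yield identical bytes
        path.write_bytes(gzip.compress(payload, mtime=0))
    else:
        path.write_bytes(payload + b"\n")


def read_domain(path) -> IntervalDomain:
    path = Path(path)
    raw = path.read_bytes()
    if path.suffix == ".ivdz":
        raw = gzip.decompress(raw)
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise DomainFormatError(f"malformed JSON in {path}: {exc}") from exc
    return domain_from_dict(doc)


# ----------------------------------------------------------------------
# NIfTI volumes
# ----------------------------------------------------------------------
def write_volume(vol: GreyVolume, path) -> None:
    """Write a grey volume as single-component NIfTI-1 (x fastest on disk)."""
    sx, sy, sz = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.data).T, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_volume(path, frame_id: str | None = None) -> GreyVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a single-component 3D volume, got {data.ndim}D data in {path}"
        )
    zooms = img.header.get_zooms()[:3]
    arr = np.ascontiguousarray(data.T)  # back to [z, y, x]
    frame = Frame(frame_id or Path(str(path)).stem, arr.shape)
    return GreyVolume(arr, spacing=tuple(float(z) for z in zooms), frame=frame)


# ----------------------------------------------------------------------
# 2D mask images
# ----------------------------------------------------------------------
def write_mask_image(domain: IntervalDomain, path, shape=None) -> None:
    """2D domain as an 8-bit PNG/TIFF mask (255 inside, 0 outside)."""
    if domain.dim != 2:
        raise ValueError("mask images are 2D")
    mask = to_mask(domain, shape)
    iio.imwrite(str(path), (mask.astype(np.uint8) * 255))


def read_mask_image(path, frame: Frame | None = None) -> IntervalDomain:
    img = np.asarray(iio.imread(str(path)))
    if img.ndim == 3:
        img = img[..., :3].max(axis=2)
    return from_mask(img > 0, frame)


# ----------------------------------------------------------------------
# index (label) volumes
# ----------------------------------------------------------------------
def export_index_volume(
    compound: CompoundObject, policy: str = "error"
) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Flatten a compound object to a one-label-per-voxel index volume.

    Returns ``(labels, table, n_overridden)``: an int32 ``[z, y, x]``
    array of layer ids (0 = background), a table mapping ids to layer
    names, and the number of voxel assignments overridden by overlaps.

    policy : ``"error"`` aborts on the first voxel covered by two or
        more layers, reporting its coordinate — an index image cannot
        represent patterns that share locations.  ``"priority"`` lets
        the last listed layer win and counts the overridden voxels.
    """
    if policy not in ("error", "priority"):
        raise ValueError(f"unknown policy {policy!r}")
    frame = compound.frame
    if frame is None:
        raise ValueError("compound layers need a frame with a grid shape")
    labels = np.zeros(frame.shape, dtype=np.int32)
    overridden = 0
    rows = []
    for idx, layer in enumerate(compound.layers, start=1):
        mask = to_mask(layer.domain, frame.shape)
        clash = mask & (labels != 0)
        if clash.any():
            if policy == "error":
                coord = tuple(int(c) for c in np.argwhere(clash)[0])
                raise IndexOverlapError(
                    f"layer {layer.name!r} overlaps a previous layer at voxel "
                    f"{coord}: an index image cannot encode two patterns at "
                    "the same location (use a compound object, or "
                    "policy='priority')"
                )
            overridden += int(clash.sum())
        labels[mask] = idx
        rows.append({"id": idx, "name": layer.name})
    return labels, pd.DataFrame(rows), overridden


def write_index_volume(
    compound: CompoundObject,
    path,
    policy: str = "error",
    spacing=(1.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, int]:
    """Export to NIfTI plus a sidecar ``<path>.labels.tsv`` table."""
    labels, table, overridden = export_index_volume(compound, policy)
    write_volume(GreyVolume(labels, spacing=spacing, frame=compound.frame), path)
    table.to_csv(f"{path}.labels.tsv", sep="\t", index=False)
    return table, overridden


# ----------------------------------------------------------------------
# heatmap rendering
# ----------------------------------------------------------------------
def render_heatmap(occ: OccupancyMap, palette: dict | None = None) -> np.ndarray:
    """Occupancy classes to RGB: class 0..3 through the palette
    (default blue / green / yellow / red).  Works for 2D maps (one
    image) and 3D maps (one image per plane, leading axis)."""
    palette = palette or FIG_PALETTE
    lut = np.zeros((4, 3), dtype=np.uint8)
    for cls, colour in palette.items():
        lut[cls] = colour
    return lut[occ.classes]


# ----------------------------------------------------------------------
# pattern manifests
# ----------------------------------------------------------------------
def write_manifest(patterns: Sequence[ExpressionPattern], out_dir) -> Path:
    """Write one ``.ivd`` per (entry, level) plus a ``patterns.tsv`` index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pat in patterns:
        for level, dom in pat.levels.items():
            fname = f"{pat.entry_id.replace(':', '_')}.{level}.ivd"
            write_domain(dom, out_dir / fname)
            rows.append(
                {
                    "entry_id": pat.entry_id,
                    "gene": pat.gene,
                    "stage": pat.stage,
                    "level": level,
                    "path": fname,
                }
            )
    manifest = out_dir / "patterns.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_manifest(path) -> list[ExpressionPattern]:
    """Load a pattern database from a manifest TSV.

    (entry_id, level) pairs must be unique and every referenced domain
    file must exist.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"entry_id", "gene", "stage", "level", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["entry_id", "level"])
    if dup.any():
        raise ValueError(
            f"duplicate (entry_id, level) rows: {df.loc[dup, 'entry_id'].tolist()}"
        )
    patterns = []
    for entry_id, grp in df.groupby("entry_id", sort=True):
        levels = {}
        for _, row in grp.iterrows():
            fpath = path.parent / row["path"]
            if not fpath.exists():
                raise FileNotFoundError(f"domain file missing: {fpath}")
            levels[row["level"]] = read_domain(fpath)
        first = grp.iloc[0]
        patterns.append(
            ExpressionPattern(
                entry_id=str(entry_id),
                gene=str(first["gene"]),
                stage=str(first["stage"]),
                levels=levels,
            )
        )
    return patterns


def read_compound_json(path, domain_root=None) -> CompoundObject:
    """Compound-object description: JSON list of
    ``{name, path, colour, alpha, visible?}`` with ``path`` pointing at a
    ``.ivd`` file (relative to the JSON file unless ``domain_root``)."""
    path = Path(path)
    root = Path(domain_root) if domain_root else path.parent
    doc = json.loads(path.read_text())
    layers = []
    for entry in doc:
        layers.append(
            Layer(
                name=entry["name"],
                domain=read_domain(root / entry["path"]),
                colour=parse_colour(entry.get("colour", "#ff0000")),
                alpha=float(entry.get("alpha", 1.0)),
                visible=bool(entry.get("visible", True)),
            )
        )
    return CompoundObject(layers)
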