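"""Syn-expression discovery: clustering of Jaccard signatures, spatial
heatmaps, occupancy maps and per-voxel gene lookup.

Each expression pattern is compared with every other in a pairwise
fashion, giving a *signature* of Jaccard similarity scores per pattern
(one row of the pairwise matrix).  Hierarchical (agglomerative)
clustering of these signatures groups genes whose expression domains
share a similar overlap profile across the whole set — syn-expression
groups — even when the domains are not mapped to identical coordinates.
Every node of the merge tree can be rendered as a spatial heatmap: the
per-voxel count of member domains containing that voxel.

Occupancy maps generalise the node heatmap to arbitrary domain lists and
carry the four display classes used for co-expression browsing:
count 0, 1, 2 and 3-or-more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from .intervals import Frame, IntervalDomain
from .similarity import ExpressionPattern

__all__ = [
    "ClusterTree",
    "OccupancyMap",
    "CLASS_NAMES",
    "signatures",
    "build_tree",
    "cut_tree",
    "node_heatmap",
    "occupancy_map",
    "voxel_query",
]

#: occupancy display classes: per-voxel pattern count capped at 3
CLASS_NAMES = {0: "zero", 1: "single", 2: "dual", 3: "three-plus"}


@dataclass
class OccupancyMap:
    """Per-voxel count of contributing domains within a reference frame.

    ``classes`` caps the count at 3 (the "three-plus" class).
    """

    counts: np.ndarray
    frame: Frame | None = None

    @property
    def classes(self) -> np.ndarray:
        return np.minimum(self.counts, 3)

    def class_names(self) -> np.ndarray:
        lut = np.array([CLASS_NAMES[i] for i in range(4)])
        return lut[self.classes]


@dataclass
class ClusterTree:
    """Binary agglomerative merge tree over expression-pattern signatures.

    Wraps a scipy linkage matrix plus the leaf entry ids; merge heights
    are non-decreasing from leaves to root and identical signatures merge
    at height 0.
    """

    entry_ids: list[str]
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix; empty for n == 1
    method: str = "average"
    metric: str = "euclidean"
    _heatmaps: dict[int, "OccupancyMap"] = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.entry_ids)

    def node_members(self, node_index: int) -> frozenset[str]:
        """Entry ids under a node.  Leaves are 0..n-1; internal node i
        (n <= i <= 2n-2) is the merge created at linkage row i - n."""
        n = self.n_leaves
        if node_index < n:
            return frozenset([self.entry_ids[node_index]])
        row = self.linkage[node_index - n]
        return self.node_members(int(row[0])) | self.node_members(int(row[1]))

    def node_height(self, node_index: int) -> float:
        n = self.n_leaves
        if node_index < n:
            return 0.0
        return float(self.linkage[node_index - n, 2])

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def cut(self, k: int) -> list[frozenset[str]]:
        return cut_tree(self, k)

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""

        def rec(i: int, parent_h: float) -> str:
            h = self.node_height(i)
            bl = parent_h - h
            if i < self.n_leaves:
                return f"{self.entry_ids[i]}:{bl:g}"
            row = self.linkage[i - self.n_leaves]
            left, right = rec(int(row[0]), h), rec(int(row[1]), h)
            return f"({left},{right}):{bl:g}"

        if self.n_leaves == 1:
            return f"{self.entry_ids[0]}:0;"
        i = self.root
        h = self.node_height(i)
        row = self.linkage[i - self.n_leaves]
        return f"({rec(int(row[0]), h)},{rec(int(row[1]), h)});"


def signatures(m: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-pattern signature vectors: row i of the pairwise Jaccard matrix.

    The matrix must be symmetric with unit diagonal (as produced by
    :func:`emas.similarity.pairwise_matrix`).
    """
    if isinstance(m, pd.DataFrame):
        ids = list(m.index)
        arr = m.to_numpy(dtype=float)
    else:
        arr = np.asarray(m, dtype=float)
        ids = list(range(arr.shape[0]))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("pairwise matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("pairwise matrix must be symmetric")
    if not np.allclose(np.diag(arr), 1.0, atol=1e-12):
        raise ValueError("pairwise matrix must have unit diagonal")
    return pd.DataFrame(arr, index=ids, columns=ids)


def build_tree(
    sigs: pd.DataFrame,
    linkage: str = "average",
    sig_distance: str = "euclidean",
) -> ClusterTree:
    """Agglomerative clustering of signature rows.

    Default: UPGMA (average linkage) on Euclidean distances between
    signature vectors.  Deterministic for a fixed input ordering.
    Passing ``sig_distance="one-minus-jaccard"`` clusters directly on
    1 − J distances instead of signature rows (comparison mode).
    """
    ids = [str(i) for i in sigs.index]
    if len(ids) == 0:
        raise ValueError("at least one signature required")
    if len(ids) == 1:
        return ClusterTree(ids, np.empty((0, 4)), linkage, sig_distance)
    if sig_distance == "one-minus-jaccard":
        from scipy.spatial.distance import squareform

        dist = 1.0 - sigs.to_numpy(dtype=float)
        np.fill_diagonal(dist, 0.0)
        z = sch.linkage(squareform(dist, checks=False), method=linkage)
    else:
        z = sch.linkage(sigs.to_numpy(dtype=float), method=linkage, metric=sig_distance)
    return ClusterTree(ids, z, linkage, sig_distance)


def cut_tree(tree: ClusterTree, k: int) -> list[frozenset[str]]:
    """Partition into ``k`` groups by removing the k−1 highest merges.

    Groups are returned in order of first appearance of a member.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return [frozenset(tree.entry_ids)]
    labels = sch.cut_tree(tree.linkage, n_clusters=k).ravel()
    groups: dict[int, set[str]] = {}
    order: list[int] = []
    for eid, lab in zip(tree.entry_ids, labels):
        if lab not in groups:
            groups[lab] = set()
            order.append(lab)
        groups[lab].add(eid)
    return [frozenset(groups[lab]) for lab in order]


def _resolve_frame(
    domains: Sequence[IntervalDomain], frame: Frame | None
) -> tuple[Frame | None, tuple[int, ...]]:
    frames = {d.frame for d in domains}
    if frame is None:
        if len(frames) > 1:
            raise ValueError(f"domains span multiple frames: {frames}")
        frame = next(iter(frames)) if frames else None
    elif frames - {frame}:
        raise ValueError("domains do not share the requested frame")
    if frame is None:
        raise ValueError("a frame (with grid shape) is required for occupancy maps")
    return frame, frame.shape


def occupancy_map(
    domains: Sequence[IntervalDomain], frame: Frame | None = None
) -> OccupancyMap:
    """Per-voxel count of how many domains contain each voxel.

    The display classes are count 0 ("zero"), 1 ("single"), 2 ("dual")
    and >= 3 ("three-plus"), conventionally rendered blue / green /
    yellow / red (see :func:`emas.io.render_heatmap`).
    """
    frame, shape = _resolve_frame(domains, frame)
    counts = np.zeros(shape, dtype=np.int32)
    view = counts[None] if len(shape) == 2 else counts
    for dom in domains:
        for z, y, s, e in dom.iter_runs():
            view[z, y, s:e] += 1
    return OccupancyMap(counts, frame)


def node_heatmap(
    node: int | Iterable[str],
    tree: ClusterTree | None,
    patterns: Sequence[ExpressionPattern],
    level: str = "detected",
) -> OccupancyMap:
    """Spatial heatmap of a tree node: per-voxel count of member domains.

    ``node`` is either a node index into ``tree`` or an explicit iterable
    of entry ids (``tree`` may then be None).  Heatmaps of tree nodes are
    cached on the tree.
    """
    cache_key = None
    if isinstance(node, (int, np.integer)):
        if tree is None:
            raise ValueError("a tree is required to resolve a node index")
        cache_key = int(node)
        if cache_key in tree._heatmaps:
            return tree._heatmaps[cache_key]
        members = tree.node_members(cache_key)
    else:
        members = frozenset(node)
    by_id = {p.entry_id: p for p in patterns}
    missing = members - by_id.keys()
    if missing:
        raise KeyError(f"patterns not supplied for members: {sorted(missing)}")
    doms = [by_id[eid].levels[level] for eid in sorted(members)]
    occ = occupancy_map(doms)
    if cache_key is not None and tree is not None:
        tree._heatmaps[cache_key] = occ
    return occ


def voxel_query(
    point: Sequence[int],
    patterns: Sequence[ExpressionPattern],
    anatomy=None,
) -> tuple[list[str], list[str]]:
    """Genes expressed at a voxel, and the anatomy layers containing it.

    ``point`` is a grid coordinate in array order.  ``anatomy`` is an
    optional compound object whose layer names are reported.  The point
    must lie within the (common) frame.
    """
    frames = {p.frame for p in patterns}
    if anatomy is not None:
        frames |= {anatomy.frame}
    frames.discard(None)
    for fr in frames:
        if any(not (0 <= int(c) < s) for c, s in zip(point, fr.shape)):
            raise ValueError(f"point {tuple(point)} outside frame {fr.id!r} {fr.shape}")
    genes = sorted(
        {p.gene for p in patterns if p.detected.contains_point(point)}
    )
    terms = []
    if anatomy is not None:
        terms = [
            layer.name
            for layer in anatomy.layers
            if layer.domain.contains_point(point)
        ]
    return genes, terms
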