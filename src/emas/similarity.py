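"""Spatial similarity scoring and ranked query over mapped expression patterns.

Two scores are provided:

* ``jaccard`` — the global intersection-over-union |A∩B| / |A∪B|, the
  score behind "find similar" ranking: a pattern queried against a
  database that contains it returns itself first with the highest
  possible coefficient of 1.
* ``lossst`` — the local spatial similarity score used for painted
  region-of-interest queries.  Expression far from the query region is
  irrelevant to a local query, so the comparison is restricted to the
  r-neighbourhood of the query::

      lossst(q, e, r) = |q ∩ e| / |q ∪ (e ∩ dilate(q, r))|

  i.e. a Jaccard score in which expression outside ``dilate(q, r)`` is
  discarded from the denominator.  With a large radius it reduces to the
  global Jaccard score; it is never smaller than it.

Both operate on interval-coded domains in a single reference frame, so a
query runs per interval, not per voxel, and scales to thousands of mapped
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Frame, IntervalDomain, intersection_size, is_subset
from .morphology import StructuringSpec, dilate

__all__ = [
    "ExpressionPattern",
    "SimilarityHit",
    "LEVELS",
    "jaccard",
    "lossst",
    "rank_query",
    "pairwise_matrix",
]

#: expression-strength vocabulary, strongest first; "detected" is the
#: union of everything annotated and must contain every other level.
LEVELS = ("strong", "moderate", "weak", "detected")


@dataclass
class ExpressionPattern:
    """A curated assay entry mapped into a reference frame.

    ``levels`` maps strength level names to interval domains, all in the
    pattern's frame.  The "detected" level must be present and must be a
    superset of every other level.
    """

    entry_id: str
    gene: str
    stage: str
    levels: dict[str, IntervalDomain]
    frame: Frame | None = None

    def __post_init__(self):
        if "detected" not in self.levels:
            raise ValueError(f"{self.entry_id}: 'detected' level is required")
        det = self.levels["detected"]
        for name, dom in self.levels.items():
            if dom.frame != det.frame:
                raise ValueError(f"{self.entry_id}: level {name!r} in a different frame")
            if name != "detected" and not is_subset(dom, det):
                raise ValueError(
                    f"{self.entry_id}: level {name!r} is not contained in 'detected'"
                )
        if self.frame is None:
            self.frame = det.frame

    @property
    def detected(self) -> IntervalDomain:
        return self.levels["detected"]


@dataclass(frozen=True)
class SimilarityHit:
    entry_id: str
    gene: str
    score: float
    method: str
    rank: int = field(default=0, compare=False)

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def jaccard(a: IntervalDomain, b: IntervalDomain) -> float:
    """Intersection-over-union |A∩B| / |A∪B| in [0, 1].

    Requires a common frame; undefined (error) when both are empty.
    """
    inter = intersection_size(a, b)  # also enforces the frame check
    denom = a.size + b.size - inter
    if denom == 0:
        raise ValueError("Jaccard undefined for two empty domains")
    return inter / denom


def lossst(
    query: IntervalDomain,
    expr: IntervalDomain,
    r: int = 2,
    connectivity: int | None = None,
) -> float:
    """Local spatial similarity score in [0, 1].

    Expression outside the ``r``-dilation of the query is ignored; within
    that neighbourhood the score is the Jaccard coefficient of query and
    (localised) expression.  ``connectivity`` defaults to 8 in 2D, 26 in 3D.
    """
    if query.is_empty:
        raise ValueError("LOSSST requires a nonempty query domain")
    if connectivity is None:
        connectivity = 8 if query.dim == 2 else 26
    inter = intersection_size(query, expr)
    halo = dilate(query, StructuringSpec(radius=r, connectivity=connectivity))
    local_expr_size = intersection_size(expr, halo)
    # |q ∪ (e ∩ halo)|; q ∩ (e ∩ halo) = q ∩ e since q ⊆ halo
    denom = query.size + local_expr_size - inter
    return inter / denom


def rank_query(
    query: IntervalDomain,
    db: list[ExpressionPattern],
    method: str = "jaccard",
    r: int = 2,
    level: str = "detected",
) -> list[SimilarityHit]:
    """Rank a database of mapped patterns against a query domain.

    Hits are sorted by score descending, ties broken by entry_id
    ascending; zero-scoring patterns are suppressed.
    """
    if method not in ("jaccard", "lossst"):
        raise ValueError(f"unknown method {method!r}")
    hits = []
    for pat in db:
        dom = pat.levels.get(level)
        if dom is None or dom.is_empty:
            continue
        if method == "jaccard":
            score = jaccard(query, dom)
        else:
            score = lossst(query, dom, r=r)
        if score > 0.0:
            hits.append((pat.entry_id, pat.gene, score))
    hits.sort(key=lambda h: (-h[2], h[0]))
    return [
        SimilarityHit(entry_id=e, gene=g, score=s, method=method, rank=i + 1)
        for i, (e, g, s) in enumerate(hits)
    ]


def pairwise_matrix(
    patterns: list[ExpressionPattern], level: str = "detected"
) -> pd.DataFrame:
    """Symmetric all-against-all Jaccard matrix at one strength level.

    Row/column labels are entry ids; the diagonal is exactly 1.  Every
    selected level-domain must be nonempty.
    """
    ids = [p.entry_id for p in patterns]
    doms = []
    for p in patterns:
        dom = p.levels.get(level)
        if dom is None or dom.is_empty:
            raise ValueError(f"pattern {p.entry_id!r} has no nonempty {level!r} domain")
        doms.append(dom)
    n = len(doms)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jaccard(doms[i], doms[j])
    return pd.DataFrame(m, index=ids, columns=ids)
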