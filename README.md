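# emas — interval-coded spatial informatics for embryo atlas data

`emas` re-implements the spatial engine behind curated mouse-embryo gene
expression atlases: binary spatial regions (anatomy domains, mapped in situ
hybridisation patterns, painted query regions) are stored as run-length
*interval codes* — per row, an ordered list of maximal half-open column
intervals — so set operations run per interval rather than per voxel and
scale, on average, with one fewer dimension than the image. On top of this
representation the package provides:

- **Set and morphological algebra** — union, intersection, difference,
  dilation, erosion, distance transforms, connected-component labelling,
  threshold segmentation, all over `IntervalDomain` objects in a shared
  reference frame.
- **Spatial similarity search** — the global Jaccard index
  J(A, B) = |A∩B| / |A∪B| for "find similar" ranking, and a local score
  (LOSSST) for painted region-of-interest queries,
  |q∩e| / |q ∪ (e ∩ δᵣ(q))|, which ignores expression outside the
  r-dilation δᵣ of the query.
- **Syn-expression clustering** — every pattern's row of the pairwise
  Jaccard matrix is its *signature*; hierarchical (UPGMA) clustering of
  signatures groups genes with similar overlap profiles, and every tree
  node renders as a spatial heatmap (per-voxel member counts).
- **Occupancy maps** — per-voxel counts of overlapping expression domains
  with the four display classes 0 / 1 / 2 / ≥3 (blue / green / yellow /
  red), plus per-voxel gene and anatomy lookup.
- **Expression mapping** — landmark-pair piecewise-affine warping of a raw
  2D assay image onto a stage-matched model, with HSV colour-threshold
  signal extraction at nested strength levels (strong ⊆ moderate ⊆ weak ⊆
  detected).
- **Virtual sectioning** — cut a 2D section at any orientation
  (pitch/yaw/roll/distance about a fixed point) through a 3D volume and
  its freely overlapping domain layers, composite RGBA overlays, serve
  fixed-size tiles.

Audience: developmental biologists and atlas curators who need spatial
query, clustering and visualisation over mapped expression domains, and
tool builders who need a compact, canonical interchange representation
for binary image regions.

## Worked example

```python
from emas.synthetic import FixtureSpec, make_expression_set
from emas.similarity import rank_query, pairwise_matrix
from emas.clustering import signatures, build_tree, cut_tree

# 15 synthetic mapped patterns: 3 planted syn-expression groups of 5
patterns, truth = make_expression_set(FixtureSpec(seed=1))

# "find similar": query the database with one of its own patterns
hits = rank_query(patterns[0].detected, patterns, method="jaccard")
print(hits[0].entry_id, round(hits[0].score, 3))   # SYN:1000 1.0
print(hits[1].entry_id, round(hits[1].score, 3))   # SYN:1004 0.864

# syn-expression discovery: cluster Jaccard signatures, cut at k=3
tree = build_tree(signatures(pairwise_matrix(patterns)))
for group in cut_tree(tree, 3):
    print(sorted(group))
```

The top hit is the query entry itself at the maximum possible Jaccard
score of 1 (a pattern intersected and unioned with itself is itself); the
next hits are its jittered group-mates near J ≈ 0.86. The three recovered
groups coincide exactly with the planted ground-truth partition
(`SYN:1000–1004`, `SYN:1005–1009`, `SYN:1010–1014`).

The same workflows are available from the shell:

```sh
emas synth --kind patterns --seed 1 --out db/
emas find-similar --entry SYN:1000 --db db/patterns.tsv --out hits.tsv
emas cluster --db db/patterns.tsv --out tree
emas synth --kind volume --seed 1 --out vol/
emas section --volume vol/phantom.nii --compound vol/layers.json \
     --pitch 20 --yaw 10 --fixed-point 36 40 32 --distance 5 --out sec.png
```

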