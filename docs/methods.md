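# Methods

This note records the model, the numerical conventions and the design
choices behind `persimorph`, and what the synthetic test collections do and
do not establish about real data.

## Tree model and SWC handling

A neuron is a rooted geometric tree embedded in 3D: nodes with positions in
µm, arcs with strictly positive length weights. Process thickness (the SWC
radius column) is carried through I/O but ignored by every computation; a
descriptor function is the intended channel for encoding it if needed.

SWC parsing is two-pass, so ids need not be contiguous or sorted and a
parent may appear after its child. Files with several parent = −1 records
are rejected by default; with `forest=True` the largest connected component
is kept (real archives occasionally contain disconnected fragments, and the
Sholl recovery identity's −1 correction assumes a connected tree). Children
at exactly their parent's coordinates are collapsed into the parent with a
logged warning, because zero-length arcs would break the geodesic
descriptor. Multi-point somata are not modelled; the tree is rooted at the
first parent = −1 record.

`simplify_tree` keeps only the root, leaves and branching nodes
(undirected degree ≠ 2). The default arc weight between consecutive kept
nodes is the chord (straight-line) distance between their positions; the
`polyline` mode sums the replaced segment lengths instead and therefore
preserves root-to-node geodesic distances exactly, while chord weights can
only shorten them.

## Descriptors

Descriptor values live at nodes and are extended piecewise-linearly along
arcs, so every critical point of the function lies at a node. For the radial
(Euclidean) descriptor this deliberately ignores interior extrema of the
true distance along a straight segment — at SWC sampling density the
difference is negligible, and the PL convention is exactly what makes the
Sholl recovery identity hold without geometric corrections. Distances are
positive by default; the optional negated radial descriptor (root highest)
is supported and the persistence sweep is sign-agnostic.

## Extended persistence

The sweep totally orders nodes by (value, id) — ascending for sublevel,
by (−value, id) for superlevel — which both breaks ties deterministically
and fixes the elder rule's comparison; descriptor values on real and
synthetic trees are generic (tie-free) with probability one. Finite pairs
whose birth equals their death after tie-breaking are discarded: they carry
zero mass in the kernel density and zero cost in any matching distance. For
generic values each sweep emits exactly (#local extrema − 1) finite points;
with massive exact ties (e.g. constant fields) the discarded
zero-persistence pairs make that count an upper bound instead, which is the
intended behaviour. Merges of degree > 3 are handled in one event: all but
the eldest component die at the merge node. Each point retains its
generating and killing node ids for debugging and provenance.

The essential pair (global min, global max) is recorded once per sweep
direction, so the merged diagram contains it twice. This is intentional:
the level-set count of the radial descriptor at a non-critical radius r is
(# sublevel points with b ≤ r ≤ d) + (# superlevel points with d ≤ r ≤ b)
− 1, and the −1 cancels exactly the doubled essential class.

Complexity is sort-dominated, O(n log n). The O(n) special case for
descriptors monotone along every root-to-leaf path is not implemented; the
general sweep covers all descriptors at negligible extra cost.

## Vectorization

Diagram point (x, y) → weighted point (x; |y − x|): the location is the
first stored coordinate whichever sweep produced it (for superlevel points
that is the larger value), so the merged diagram vectorizes unambiguously.
Essential points are included by default — they carry the largest masses,
the total descriptor depth — with a flag to exclude them.

The density is an untruncated Gaussian mixture; the vector samples it at
a + I/m, a + 2I/m, …, b (I = b − a), so the last sample is exactly b and
the grid matches the Sholl profile discretization. The shared range [a, b]
is the min/max over all birth and death coordinates in the collection
(padding available, default 0). Summation order is canonicalized by sorting
weighted points, making the vector bit-identical under diagram point
permutation. Defaults t = 50 and m = 100 suit µm-scale distance
descriptors; t is scale-dependent and must be reconsidered for descriptors
in other units.

Multiple descriptors concatenate in fixed order to a length-r·m vector;
the optional collection-level PCA (numpy SVD) orients each component so its
largest-magnitude loading is positive, for determinism.

## Distances

Ground cost between diagram points is L∞, the convention under which
bottleneck stability is exact; a point matched to the diagonal pays
|d − b|/2. The 1-Wasserstein distance is solved exactly with
`scipy.optimize.linear_sum_assignment` on the two point sets augmented with
diagonal slots; bottleneck by binary search over the candidate costs with a
bipartite-matching feasibility test. Essential points participate in the
matching like any other point — no origin constraint is imposed, which is
the simplest consistent choice.

The L-Measure distance z-scores each feature against the analyzed
collection (zero-variance features dropped with a warning) and takes L2;
"normalized L2" admits other readings, and this one is invariant to affine
rescaling of any raw feature. The combined distance rescales each input
matrix to unit maximum before the 0.5/0.5 mix, because the vector and
morphometric distances live on incomparable scales. Neurons with missing
L-Measure features raise rather than being silently imputed.

## Classification, clustering, embedding

LOOCV k-NN: classes below `min_class_size` (default 2) are removed from the
collection entirely before evaluation — a singleton has no same-class
neighbor to find, and keeping it in the candidate pool would only add noise.
Distance ties at the k-th neighbor resolve toward the lexicographically
smaller name, so results are order-independent. SR_k is non-decreasing in k
by construction. The bootstrap subsamples without replacement.

UPGMA is delegated to `scipy.cluster.hierarchy.linkage`; exact merge ties
therefore follow scipy's internal order rather than a lexicographic rule
(distinct-distance inputs, the generic case, are unaffected). The Newick
export uses branch lengths equal to merge-height differences.

The Laplacian eigenmap builds a symmetrized kNN graph with heat-kernel
weights exp(−d²/σ²), σ = median included distance; structural edges are
floored at 1e−12 so far-apart cluster pairs weaken but never sever the
graph (a genuinely disconnected kNN graph still raises). Coordinates come
from the two smallest non-trivial eigenvectors of the symmetric normalized
Laplacian, sign-fixed like the PCA components. The graph construction
parameters are visualization choices, not part of any quantitative result.

## Synthetic data

The generator emulates SWC-style neurites, not biophysics: at each step an
active tip bifurcates with probability `branch_prob` (while its bifurcation
depth is below `max_depth`), and each resulting tip extends by a log-normal
segment (mean length, CV) in a direction drawn within a spherical cap
around its parent direction. Defaults — branch probability 0.3, CV 0.3,
depth cap 6, cap half-angle 0.6 rad, 12 steps — give trees of a few dozen
to ~100 nodes with realistic-looking meander and branch-order statistics.
The three-class study collection (20 trees per class, mean segment lengths
10 / 50 / 250 µm) plants class structure in overall cable scale, the signal
a geodesic-descriptor summary should recover; per-tree seeds are spawned
deterministically from the collection seed and (class, tree) indices.

What passing tests on this collection shows: the pipeline's invariances,
identities and exactness guarantees, and that well-separated scale classes
are recovered essentially perfectly. What it does not show: performance on
real archives, where classes differ in subtler branching statistics,
reconstructions carry protocol artifacts, and class counts are unbalanced —
`scripts/reproduce_neuromorpho.py` exists for that purpose and requires
downloaded data.

## Problem sizes and tolerances

The test suite works at desk scale by choice: oracle-equivalence trees at
≤ 50 nodes (brute-force component recomputation is cubic-ish), Sholl
identity trees at ≤ 200 nodes with 50 random non-critical radii each,
matching exactness on diagrams of ≤ 4 points (exhaustive enumeration),
stability at ε = 0.01 on 20 trees. Identity checks are exact integer
comparisons; floating-point comparisons use 1e−9 where an assignment or
eigen-solve is involved and 1e−12 for pure re-orderings of the same
arithmetic. Radii within 1e−9 of a node value are treated as critical and
excluded from the Sholl identity, which is stated for non-critical radii.

## Known limitations

- Vineyards (time-varying diagrams) are out of scope; the diagram API keeps
  per-point node provenance so a vineyard layer could be added on top.
- No cable-equation solver: electrotonic descriptors must be computed
  externally and supplied via `descriptor_from_values`.
- The Wasserstein solver is dense O(k³); fine for diagrams up to a few
  hundred points, not tuned for whole-archive d_P matrices.
- Sholl counts use the PL level-set convention, not geometric chord–sphere
  intersections; the two differ on segments that cross a sphere twice
  between samples.
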