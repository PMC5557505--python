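# persimorph

Persistence-based feature vectorization and comparison of neuronal tree
morphologies.

Comparing neuron reconstructions is a basic need in neuroanatomy: given
thousands of SWC files from archives such as NeuroMorpho.Org, one wants
distances between cells that respect both local branching detail and global
tree shape, and that are cheap enough for nearest-neighbor search, clustering
and indexing. Simple morphometric summaries (mean branch angle, partition
asymmetry, ...) discard the global structure; tree-edit distances keep it but
are expensive. `persimorph` takes the topological middle road: it summarizes a
*descriptor function* on the neuron tree by its extended persistence diagram
and turns that diagram into a fixed-length Euclidean feature vector.

## The method

Model a neuron as a rooted geometric tree *T* embedded in 3D with root *r*
(the soma). Choose a descriptor function *f* on *T* — by default the
**geodesic distance** g(x) = path length from *r* to *x*, or the **Euclidean
(radial) distance** ‖x − r‖ — extended piecewise-linearly along arcs. Then:

1. **Extended persistence diagram.** Sweep the sublevel sets
   {x : f(x) ≤ t} upward and the superlevel sets {x : f(x) ≥ t} downward,
   tracking connected components. Each merge kills the younger component
   (elder rule) and records a point (f(m), f(s)) — birth at the extremum
   *m*, death at the merge node *s*. The union of both sweeps, plus the
   essential pair coupling the global minimum and maximum of *f* (once per
   sweep), is the diagram D̂g f. Computed in O(n log n) by a union-find
   sweep.
2. **Persistence vector.** Each diagram point (x, y) becomes a weighted
   point on the line at x with mass |y − x|; the weighted Gaussian density
   ρ_D(s) = Σᵢ mᵢ exp(−(s − xᵢ)²/2t²) is sampled at m positions evenly
   spaced over a range [a, b] shared across the collection. Defaults:
   kernel width t = 50 (descriptor units), dimension m = 100.
3. **Distances.** d_P = degree-1 Wasserstein between diagrams (exact, via
   optimal assignment with diagonal projections); d_V = L1 between
   persistence vectors; d_S = L1 between 100-point Sholl profiles; d_L =
   z-scored L2 between external L-Measure feature vectors; d_C = an
   equal-weight mix of rescaled d_V and d_L. Bottleneck distance is included
   for stability analysis.
4. **Analysis.** Leave-one-out k-NN success rates SR_k (a query is a hit if
   any of its k nearest neighbors shares its class), bootstrap variability,
   average-linkage (UPGMA) dendrograms with Newick export, and a Laplacian
   eigenmap 2D embedding.

A classical connection: with the radial descriptor, the Sholl intersection
count N(r) — the number of crossings of the radius-r sphere about the soma —
is exactly recoverable from the diagram as

    N(r) = #{(b, d) ∈ Dg⊥ : b ≤ r ≤ d} + #{(b, d) ∈ Dg⊤ : d ≤ r ≤ b} − 1,

so the persistence summary is strictly more informative than the Sholl
profile. `persimorph.sholl` implements both sides of this identity and the
test suite verifies it exactly on thousands of random radii.

## Worked example

```python
import persimorph as pm
from persimorph.synthgen import GrowthParams, generate_labeled_collection

class_params = [(f"class{i}", GrowthParams(mean_segment_length=L), 20)
                for i, L in enumerate([10.0, 50.0, 250.0])]
trees, labels = generate_labeled_collection(class_params, collection_seed=0)

diagrams = [pm.extended_diagram(pm.geodesic_descriptor(t)) for t in trees]
a, b = pm.collection_range(diagrams)
cfg = pm.SignatureConfig(kernel_width=50.0, dimension=100, a=a, b=b)
vectors = [pm.vectorize(d, cfg) for d in diagrams]
dv = pm.pairwise_matrix(vectors, pm.lp_vector_distance,
                        names=[t.name for t in trees], metric_name="dV")
coll = pm.LabeledCollection(distance=dv, labels=labels)
for k in (1, 5):
    print(k, pm.knn_loocv(coll, k).success_rate)
```

prints

```
1 0.9833333333333333
5 0.9833333333333333
```

i.e. leave-one-out 1-NN classification assigns 59 of the 60 synthetic neurons
to the correct growth class from the persistence vector of a single geodesic
descriptor.

The same pipeline is available from the shell:

```bash
persimorph synth --out data --classes 3 --per-class 20 --seed 0
persimorph distances data --out dv.csv --metric dV
persimorph classify dv.csv data/labels.tsv --out knn.json
persimorph cluster dv.csv --out clusters
persimorph sholl data --out sholl --verify
```

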