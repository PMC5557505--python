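#!/usr/bin/env python
"""Re-run the k-NN classification protocol on real NeuroMorpho.Org
reconstructions (requires a prior download; nothing in the test suite or the
acceptance script depends on this).

Expected layout (assemble it yourself from https://neuromorpho.org — e.g. the
Purkinje, olivocerebellar, spinal motoneuron and hippocampal interneuron
archives):

    <data-dir>/
        labels.tsv          # "<filename>.swc<TAB><class>" per line
        *.swc               # standard 7-column reconstructions

Protocol: trees are simplified to root/branch/leaf skeletons with chord arc
weights; the geodesic-distance descriptor is summarized by its extended
persistence diagram; diagrams are vectorized with a Gaussian kernel of width
50 µm into 100-dimensional persistence vectors over the shared collection
range; leave-one-out k-NN success rates SR_1..SR_5 are reported for the L1
vector distance.  Classes with fewer than 2 members are dropped.

Usage:  python scripts/reproduce_neuromorpho.py <data-dir>
"""

from __future__ import annotations

import argparse
from pathlib import Path

from persimorph.analysis import LabeledCollection, knn_loocv
from persimorph.descriptors import geodesic_descriptor
from persimorph.metrics import lp_vector_distance, pairwise_matrix
from persimorph.persistence import extended_diagram
from persimorph.signatures import SignatureConfig, collection_range, vectorize
from persimorph.swc_io import read_swc, simplify_tree


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("data_dir", type=Path)
    parser.add_argument("--k-max", type=int, default=5)
    args = parser.parse_args()

    labels: dict[str, str] = {}
    for line in (args.data_dir / "labels.tsv").read_text().splitlines():
        if line.strip():
            fname, cls = line.split("\t")
            labels[fname.removesuffix(".swc")] = cls

    trees = []
    for path in sorted(args.data_dir.glob("*.swc")):
        if path.stem not in labels:
            continue
        # real archives occasionally contain disconnected fragments
        trees.append(simplify_tree(read_swc(path, forest=True)))
    print(f"loaded {len(trees)} reconstructions")

    diagrams = [extended_diagram(geodesic_descriptor(t)) for t in trees]
    a, b = collection_range(diagrams)
    cfg = SignatureConfig(kernel_width=50, dimension=100, a=a, b=b)
    vectors = [vectorize(dg, cfg) for dg in diagrams]
    matrix = pairwise_matrix(
        vectors, lp_vector_distance, names=[t.name for t in trees], metric_name="dV"
    )
    coll = LabeledCollection(distance=matrix, labels=labels)
    for k in range(1, args.k_max + 1):
        res = knn_loocv(coll, k)
        print(f"k={k}: {res.hits}/{res.n_evaluated} hits, SR={res.success_rate:.4f}")


if __name__ == "__main__":
    main()
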