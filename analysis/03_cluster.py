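"""Cluster the gene signature rows: uncentered correlation, average linkage.

Hierarchical cluster analysis of S in the Cluster 3.0 manner, cut into
(modules + 1) flat clusters.  Writes the dendrogram in CDT/GTR form (viewable
in Java TreeView), the flat assignments, and reports how the planted modules
map onto the clusters.

Inputs:  results/S.tsv, results/truth.tsv
Outputs: results/clusters.tsv, results/tree.cdt, results/tree.gtr
"""

import argparse
from collections import Counter
from pathlib import Path

from icamod import cut_tree, hca
from icamod.io_formats import (
    read_expression_tsv,
    write_cdt_gtr,
    write_cluster_assignments,
)
from icamod.synthetic_data import read_truth_tsv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cut-k", type=int, default=4)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    sig = read_expression_tsv(args.out_dir / "S.tsv")
    truth = read_truth_tsv(args.out_dir / "truth.tsv")
    dendro = hca(sig.values, sig.gene_ids, similarity="uncentered", linkage="average")
    assignment = cut_tree(dendro, n_clusters=args.cut_k)
    write_cluster_assignments(assignment, args.out_dir / "clusters.tsv",
                              comments=[f"cut at {args.cut_k} clusters"])
    write_cdt_gtr(sig.gene_ids, sig.values, dendro, args.out_dir / "tree")

    print(f"{dendro.n_leaves} genes, {len(dendro.merges)} merges, "
          f"cut into {assignment.n_clusters} clusters")
    for label, members in assignment.cluster_members().items():
        composition = Counter(truth.module_of_gene[g] for g in members)
        desc = ", ".join(f"{mod}: {cnt}" for mod, cnt in composition.most_common())
        print(f"  cluster {label} ({len(members)} genes): {desc}")
    print(f"wrote {args.out_dir / 'clusters.tsv'}, tree.cdt, tree.gtr")


if __name__ == "__main__":
    main()
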