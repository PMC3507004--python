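"""Recovery scoring against planted truth, and the IC-number sweep.

Two external-validation statistics: the adjusted Rand index between the
flat clustering and the planted partition (background genes count as their
own module, since the background dominates a compendium-scale matrix and a
good clustering must separate it), and a per-module best-match Jaccard.
The sweep re-runs decomposition + clustering for a list of component
numbers k and tabulates where any dual-membership gene lands at each k —
the membership of a bifunctional gene can legitimately shift with k.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np

from .clustering import ClusterAssignment, cut_tree, hca
from .ica_core import ContrastFunction, fastica
from .io_formats import ExpressionMatrix
from .synthetic_data import BACKGROUND_LABEL, SyntheticTruth


@dataclass
class RecoveryReport:
    """Recovery quality of one decompose-and-cluster run."""

    k: int
    ari: float
    per_module: list[tuple[str, int, float]]  # (module, best cluster, jaccard)
    dual_gene_assignments: dict[str, str]  # gene -> module of its cluster (or "unassigned")
    n_clusters: int

    def jaccard_of(self, module: str) -> float:
        for name, _, j in self.per_module:
            if name == module:
                return j
        raise KeyError(module)


def _check_universe(assignment: ClusterAssignment, truth: SyntheticTruth) -> None:
    a = set(assignment.labels)
    b = set(truth.module_of_gene)
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise ValueError(f"gene universes differ; symmetric difference: {', '.join(diff)}")


def ari_from_labels(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings of the same items.

    Pair-counting form under the permutation null:
    (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2).
    Degenerate pairs where max == E (e.g. all-singletons vs all-together)
    return 0 by convention.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must cover the same items")
    n = len(labels_a)
    contingency: dict[tuple, int] = {}
    count_a: dict[object, int] = {}
    count_b: dict[object, int] = {}
    for la, lb in zip(labels_a, labels_b):
        contingency[(la, lb)] = contingency.get((la, lb), 0) + 1
        count_a[la] = count_a.get(la, 0) + 1
        count_b[lb] = count_b.get(lb, 0) + 1
    index = sum(comb(nij, 2) for nij in contingency.values())
    sum_a = sum(comb(c, 2) for c in count_a.values())
    sum_b = sum(comb(c, 2) for c in count_b.values())
    total = comb(n, 2)
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 0.0
    return float((index - expected) / (maximum - expected))


def adjusted_rand_index(assignment: ClusterAssignment, truth: SyntheticTruth) -> float:
    """ARI between a flat clustering and the planted module partition."""
    _check_universe(assignment, truth)
    genes = truth.gene_ids
    return ari_from_labels(
        [assignment.labels[g] for g in genes],
        [truth.module_of_gene[g] for g in genes],
    )


def module_jaccard(
    assignment: ClusterAssignment, truth: SyntheticTruth
) -> list[tuple[str, int, float]]:
    """Best-match Jaccard of each planted module against the clusters.

    Ties between clusters are broken toward the smaller cluster label.
    """
    _check_universe(assignment, truth)
    members = assignment.cluster_members()
    out = []
    for module in truth.module_names:
        mod_set = set(truth.members(module))
        best_label, best_j = 0, -1.0
        for label in range(assignment.n_clusters):
            cl_set = set(members[label])
            j = len(mod_set & cl_set) / len(mod_set | cl_set)
            if j > best_j:
                best_label, best_j = label, j
        out.append((module, best_label, best_j))
    return out


def score_assignment(
    assignment: ClusterAssignment, truth: SyntheticTruth, k: int
) -> RecoveryReport:
    """Bundle ARI, per-module Jaccard and dual-gene placements into a report."""
    per_module = module_jaccard(assignment, truth)
    best_cluster = {module: label for module, label, _ in per_module}
    dual = {}
    for gid in truth.dual_genes:
        cluster = assignment.labels[gid]
        hit = [m for m, lab in best_cluster.items() if lab == cluster]
        dual[gid] = hit[0] if hit else "unassigned"
    return RecoveryReport(
        k=k,
        ari=adjusted_rand_index(assignment, truth),
        per_module=per_module,
        dual_gene_assignments=dual,
        n_clusters=assignment.n_clusters,
    )


def ic_sweep(
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    k_values: Sequence[int],
    n_clusters: int,
    seed: int,
    contrast: ContrastFunction | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    similarity: str = "uncentered",
) -> list[RecoveryReport]:
    """Decompose, cluster and score for every k in ``k_values``.

    The same decomposition seed is used at every k, so differences between
    reports reflect the component number, not the initialization draw.
    """
    reports = []
    for k in k_values:
        dec = fastica(matrix, k=k, contrast=contrast, max_iter=max_iter, tol=tol, seed=seed)
        dendro = hca(dec.S, dec.gene_ids, similarity=similarity, linkage="average")
        assignment = cut_tree(dendro, n_clusters=n_clusters)
        reports.append(score_assignment(assignment, truth, k))
    return reports


def write_sweep_tsv(
    reports: Sequence[RecoveryReport], path: str | Path, comments: Sequence[str] = ()
) -> None:
    """One row per (k, module), plus dual-gene placements."""
    with Path(path).open("w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("k\tari\tmodule\tbest_cluster\tjaccard\tdual_gene\tdual_assignment\n")
        for rep in reports:
            dual_str = (
                ";".join(f"{g}={m}" for g, m in sorted(rep.dual_gene_assignments.items()))
                or "-"
            )
            for module, label, j in rep.per_module:
                fh.write(
                    f"{rep.k}\t{rep.ari!r}\t{module}\t{label}\t{j!r}\t"
                    f"{';'.join(sorted(rep.dual_gene_assignments)) or '-'}\t{dual_str}\n"
                )
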