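"""Synthetic expression compendia with planted co-regulated modules.

The generator emulates, at configurable scale, the statistical situation of a
public microarray compendium restricted to metabolism genes: a few small
pathway modules (think anthocyanin-skeleton, anthocyanin-modification and
flavonol sub-clusters of a few genes each) whose members are driven by
sparse, super-Gaussian latent activation signals across samples, embedded in
a large background of genes that respond only weakly to those shared
physiological drivers.  The data follow the linear latent model

    X = L @ sources + noise,

genes x samples, so every downstream stage (whitening, fastICA, signature
clustering, guide-gene screening, recovery scoring) can be exercised against
known ground truth without any external download.

Module members load ``loading_strength`` on their module's activation
signal.  Background genes load ``background_coupling`` (a small fraction of
the member loading) on *every* module signal, with a gene-specific
sensitivity drawn around 1: in real compendia the conditions that switch a
pathway on (stress, nutrient shifts, regulator over-expression) also move
general metabolism slightly, which is precisely what makes the uncentered
("cosine") correlation of Cluster 3.0 meaningful.  A fully idle background
would have direction-free signature rows and no clusterable structure.

An optional dual-membership gene loads on two modules at once (a bifunctional
enzyme acting in two branches of a pathway); its cluster membership is
expected to shift with the number of extracted components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

BACKGROUND_LABEL = "background"

#: Module layout used throughout the documentation and the demo pipeline;
#: sizes follow typical pathway sub-cluster sizes (a handful of genes each).
DEFAULT_MODULES: tuple[tuple[str, int], ...] = (
    ("anthocyanin_skeleton", 8),
    ("anthocyanin_modification", 6),
    ("flavonol", 10),
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic compendium.

    Defaults give a desk-scale compendium of 1000 genes x 200 samples with
    three planted modules of 8/6/10 genes.  ``seed`` controls every random
    draw; identical specs produce bitwise identical matrices.
    """

    n_genes: int = 1000
    n_samples: int = 200
    modules: tuple[tuple[str, int], ...] = DEFAULT_MODULES
    source_distribution: str = "laplace"  # or "sparse-spike"
    loading_strength: float = 1.0
    cross_loading: float = 0.8
    dual_genes: tuple[tuple[int, tuple[str, str]], ...] = ()
    noise_sd: float = 0.3
    baseline_sd: float = 0.3
    background_coupling: float = 0.12
    coupling_spread: float = 0.1
    seed: int = 7

    def validate(self) -> None:
        names = [name for name, _ in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        if any(size < 1 for _, size in self.modules):
            raise ValueError("module sizes must be positive")
        if sum(size for _, size in self.modules) > self.n_genes:
            raise ValueError(
                f"module member counts ({sum(s for _, s in self.modules)}) "
                f"exceed n_genes ({self.n_genes})"
            )
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if self.source_distribution not in ("laplace", "sparse-spike"):
            raise ValueError(f"unknown source distribution {self.source_distribution!r}")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise_sd and baseline_sd must be non-negative")
        if not 0 <= self.cross_loading <= 1:
            raise ValueError("cross_loading must be in [0, 1]")
        for idx, pair in self.dual_genes:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"dual gene index {idx} out of range")
            for name in pair:
                if name not in names:
                    raise ValueError(f"dual gene references unknown module {name!r}")

    @property
    def module_names(self) -> list[str]:
        return [name for name, _ in self.modules]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated matrix, for recovery scoring."""

    gene_ids: list[str]
    module_of_gene: dict[str, str]
    module_names: list[str]
    sources: np.ndarray | None  # k* x n_samples latent activations
    loadings: np.ndarray | None  # n_genes x k*, rows aligned with gene_ids
    dual_genes: dict[str, tuple[str, str]] = field(default_factory=dict)

    def members(self, module: str) -> list[str]:
        return [g for g in self.gene_ids if self.module_of_gene[g] == module]


def demo_spec(seed: int = 7) -> SyntheticSpec:
    """The frozen demonstration fixture: default spec plus one dual gene.

    The dual gene's primary membership is the *weaker* module
    (anthocyanin_modification, 6 members) with a 0.8 cross-loading on the
    flavonol module.  At k = 2 the weak module gets no component of its own
    and the gene defects to the flavonol cluster; from k = 3 on it sits with
    its primary module — the classic bifunctional-enzyme membership shift.
    """
    # pre-shuffle index 8 = first anthocyanin_modification member
    return SyntheticSpec(
        seed=seed,
        dual_genes=((8, ("anthocyanin_modification", "flavonol")),),
    )


def _draw_sources(rng: np.random.Generator, k: int, n: int, kind: str) -> np.ndarray:
    if kind == "laplace":
        return rng.laplace(0.0, 1.0, size=(k, n))
    # sparse-spike: silent in most conditions, occasional strong activation
    mask = rng.random(size=(k, n)) < 0.1
    amplitude = rng.normal(0.0, 3.0, size=(k, n))
    return np.where(mask, amplitude, 0.0)


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a matrix and its ground truth.

    The random stream is consumed in a fixed order (sources, coupling
    sensitivities, baseline, unit noise, row shuffle) regardless of parameter
    values, so that e.g. raising ``noise_sd`` rescales the *same* noise
    realization instead of drawing a new one — within-module correlations are
    then monotone in the noise level for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_genes, spec.n_samples
    k = len(spec.modules)

    sources = _draw_sources(rng, k, n, spec.source_distribution)
    sensitivity = rng.uniform(
        1.0 - spec.coupling_spread, 1.0 + spec.coupling_spread, size=(m, k)
    )
    baseline_unit = rng.normal(0.0, 1.0, size=(m, n))
    noise_unit = rng.normal(0.0, 1.0, size=(m, n))
    perm = rng.permutation(m)

    loadings = spec.background_coupling * spec.loading_strength * sensitivity
    labels = np.full(m, BACKGROUND_LABEL, dtype=object)
    i = 0
    for j, (name, size) in enumerate(spec.modules):
        loadings[i : i + size] = 0.0
        loadings[i : i + size, j] = spec.loading_strength
        labels[i : i + size] = name
        i += size
    n_members = i
    name_to_col = {name: j for j, name in enumerate(spec.module_names)}
    dual_pairs: dict[int, tuple[str, str]] = {}
    for idx, (primary, secondary) in spec.dual_genes:
        loadings[idx] = 0.0
        loadings[idx, name_to_col[primary]] = spec.loading_strength
        loadings[idx, name_to_col[secondary]] = spec.cross_loading * spec.loading_strength
        labels[idx] = primary
        dual_pairs[idx] = (primary, secondary)

    x = loadings @ sources
    background = labels == BACKGROUND_LABEL
    x[background] += spec.baseline_sd * baseline_unit[background]
    x += spec.noise_sd * noise_unit

    x = x[perm]
    loadings = loadings[perm]
    labels = labels[perm]

    width = max(4, len(str(m - 1)))
    gene_ids = [f"G{i:0{width}d}" for i in range(m)]
    sample_ids = [f"S{j:0{width}d}" for j in range(n)]
    module_of_gene = dict(zip(gene_ids, labels))
    pos_of_old = np.empty(m, dtype=int)
    pos_of_old[perm] = np.arange(m)
    dual_by_id = {gene_ids[pos_of_old[idx]]: pair for idx, pair in dual_pairs.items()}

    matrix = ExpressionMatrix(gene_ids, sample_ids, x)
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        module_of_gene=module_of_gene,
        module_names=list(spec.module_names),
        sources=sources,
        loadings=loadings,
        dual_genes=dual_by_id,
    )
    return matrix, truth


def excess_kurtosis(values: Sequence[float] | np.ndarray) -> float:
    """Sample excess kurtosis (fourth standardized moment minus 3).

    Positive for the sparse, heavy-tailed activation signals the generator
    plants (Laplace: 3); this is the non-Gaussianity that makes the
    components identifiable by a fixed-point ICA.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("degenerate input: constant vector has no kurtosis")
    return float(stats.kurtosis(x, fisher=True, bias=True))


def write_truth_tsv(truth: SyntheticTruth, path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write gene -> module labels (and dual memberships) as TSV."""
    with Path(path).open("w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tmodule\tsecondary_module\n")
        for gid in truth.gene_ids:
            secondary = ""
            if gid in truth.dual_genes:
                secondary = truth.dual_genes[gid][1]
            fh.write(f"{gid}\t{truth.module_of_gene[gid]}\t{secondary}\n")


def read_truth_tsv(path: str | Path) -> SyntheticTruth:
    """Read labels written by :func:`write_truth_tsv`.

    Sources and loadings are not serialized; the returned truth supports
    partition scoring (ARI, Jaccard, dual-gene tracking) but not
    loading-recovery checks.
    """
    gene_ids: list[str] = []
    module_of_gene: dict[str, str] = {}
    dual: dict[str, tuple[str, str]] = {}
    modules: list[str] = []
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")
    ]
    for ln in lines[1:]:
        parts = ln.split("\t")
        gid, module = parts[0], parts[1]
        gene_ids.append(gid)
        module_of_gene[gid] = module
        if module != BACKGROUND_LABEL and module not in modules:
            modules.append(module)
        if len(parts) > 2 and parts[2]:
            dual[gid] = (module, parts[2])
    return SyntheticTruth(
        gene_ids=gene_ids,
        module_of_gene=module_of_gene,
        module_names=modules,
        sources=None,
        loadings=None,
        dual_genes=dual,
    )
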