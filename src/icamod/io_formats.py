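"""Flat-file input/output for the expression analysis pipeline.

Every format here is plain text: tab-separated expression matrices in the
style of the ATTED-II ``GeneExp_v3`` flat file (header row of sample IDs,
first column of gene IDs), one-ID-per-line gene lists, and the Cluster 3.0
CDT/GTR dialect that Java TreeView reads.  Values are written at full float
precision so that a write/read round trip is bit-exact.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null"}


class FormatError(ValueError):
    """A file violates the expected tabular format."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression values.

    Attributes
    ----------
    gene_ids:
        Ordered, unique gene identifiers (matrix rows).
    sample_ids:
        Ordered, unique sample identifiers (matrix columns).
    values:
        Float matrix of shape ``(len(gene_ids), len(sample_ids))`` with no
        non-finite entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression_tsv(path: str | Path, impute: str | None = None) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The first row is a header whose first cell names the ID column; every
    other row is a gene ID followed by one numeric value per sample.  Lines
    starting with ``#`` before the header are treated as comments.

    Parameters
    ----------
    impute:
        ``None`` (default) rejects missing cells; ``"row-mean"`` replaces
        each missing cell with the mean of the finite values in its row.
    """
    if impute not in (None, "row-mean"):
        raise ValueError(f"unknown impute mode {impute!r}")
    path = Path(path)
    with path.open(newline="") as fh:
        rows = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        gene_ids: list[str] = []
        data: list[list[float]] = []
        missing: list[tuple[int, int]] = []  # (row index in data, col index)
        seen: set[str] = set()
        for lineno, row in enumerate(rows, start=1):
            if header is None:
                if row and row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise FormatError(f"{path}: header must name at least one sample")
                header = row
                n_cols = len(row)
                continue
            if not row:
                continue
            if len(row) != n_cols:
                raise FormatError(
                    f"{path}: ragged row at line {lineno}: expected "
                    f"{n_cols} fields, found {len(row)}"
                )
            gid = row[0]
            if gid in seen:
                raise FormatError(f"{path}: duplicate gene ID {gid!r} at line {lineno}")
            seen.add(gid)
            vals: list[float] = []
            for col, cell in enumerate(row[1:], start=2):
                token = cell.strip()
                if token.lower() in _MISSING_TOKENS:
                    if impute is None:
                        raise FormatError(
                            f"{path}: missing value at line {lineno}, column {col} "
                            "(pass impute='row-mean' to impute)"
                        )
                    missing.append((len(data), col - 2))
                    vals.append(np.nan)
                    continue
                try:
                    v = float(token)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at line {lineno}, "
                        f"column {col}"
                    ) from None
                if not np.isfinite(v):
                    if impute is None:
                        raise FormatError(
                            f"{path}: non-finite value {cell!r} at line {lineno}, "
                            f"column {col}"
                        )
                    missing.append((len(data), col - 2))
                    v = np.nan
                vals.append(v)
            gene_ids.append(gid)
            data.append(vals)
    if header is None:
        raise FormatError(f"{path}: empty file")
    if not gene_ids:
        raise FormatError(f"{path}: no gene rows")
    values = np.asarray(data, dtype=float)
    if missing:
        for i, _ in missing:
            row_vals = values[i]
            finite = row_vals[np.isfinite(row_vals)]
            if finite.size == 0:
                raise FormatError(
                    f"{path}: gene {gene_ids[i]!r} has no finite values to impute from"
                )
            values[i, ~np.isfinite(row_vals)] = finite.mean()
        logger.info("imputed %d missing cells by row mean", len(missing))
    return ExpressionMatrix(gene_ids, header[1:], values)


def write_expression_tsv(
    matrix: ExpressionMatrix,
    path: str | Path,
    id_column: str = "gene_id",
    comments: Sequence[str] = (),
) -> None:
    """Write a matrix as TSV, re-readable bit-exactly by :func:`read_expression_tsv`.

    ``comments`` are emitted as ``# ``-prefixed lines before the header
    (used for provenance stamps).
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join([id_column, *matrix.sample_ids]) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def select_genes(matrix: ExpressionMatrix, gene_list: Sequence[str]) -> ExpressionMatrix:
    """Restrict a matrix to the listed genes, in list order.

    Mirrors the AraCyc-style metabolism-gene selection applied before ICA:
    genes absent from the matrix are reported via the module logger, and an
    empty overlap is an error.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene_list is empty")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    keep = [g for g in gene_list if g in index]
    absent = [g for g in gene_list if g not in index]
    if absent:
        logger.warning("%d listed genes absent from matrix: %s", len(absent), ", ".join(absent))
    if not keep:
        raise ValueError("empty selection: no listed gene is present in the matrix")
    rows = [index[g] for g in keep]
    return ExpressionMatrix(keep, matrix.sample_ids, matrix.values[rows])


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list; ``#`` starts a comment."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out


def write_cdt_gtr(
    gene_ids: Sequence[str],
    signature: np.ndarray,
    dendrogram,
    path_stem: str | Path,
    column_ids: Sequence[str] | None = None,
) -> None:
    """Write Cluster 3.0 style ``.cdt`` / ``.gtr`` files for Java TreeView.

    The ``.gtr`` lists one merge per line (node ID, two child IDs, similarity
    at the merge); the ``.cdt`` holds the signature rows reordered to the
    dendrogram's left-to-right leaf order, with a GID column linking rows to
    tree leaves.  No comment lines are written: TreeView does not accept them.
    """
    gene_ids = list(gene_ids)
    signature = np.asarray(signature, dtype=float)
    if signature.ndim == 1:
        signature = signature[:, None]
    n = len(gene_ids)
    if dendrogram.leaves != gene_ids:
        raise ValueError("dendrogram leaves do not match signature rows")
    if signature.shape[0] != n:
        raise ValueError("signature row count does not match gene_ids")
    if column_ids is None:
        column_ids = [f"IC{j + 1}" for j in range(signature.shape[1])]

    def ref(node: int) -> str:
        return f"GENE{node}X" if node < n else f"NODE{node - n + 1}X"

    stem = Path(path_stem)
    with open(f"{stem}.gtr", "w") as fh:
        for t, m in enumerate(dendrogram.merges, start=1):
            fh.write(f"NODE{t}X\t{ref(m.left)}\t{ref(m.right)}\t{repr(float(m.similarity))}\n")
    with open(f"{stem}.cdt", "w") as fh:
        fh.write("\t".join(["GID", "UNIQID", "NAME", "GWEIGHT", *column_ids]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", ""] + ["1"] * len(column_ids)) + "\n")
        for leaf in dendrogram.leaf_order:
            row = signature[leaf]
            fh.write(
                "\t".join(
                    [f"GENE{leaf}X", gene_ids[leaf], gene_ids[leaf], "1"]
                    + [repr(float(v)) for v in row]
                )
                + "\n"
            )


def write_cluster_assignments(assignment, path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write a flat gene -> cluster table (TSV)."""
    with Path(path).open("w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tcluster\n")
        for gid, label in assignment.labels.items():
            fh.write(f"{gid}\t{label}\n")
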