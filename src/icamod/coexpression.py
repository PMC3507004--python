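"""Guide-gene Pearson-correlation screening.

The classic coexpression candidate hunt: take known pathway members as
guides, correlate every other gene against each guide across the whole
compendium, and nominate genes with two or more strong positive links
(r > 0.525 by default — the cutoff used with ATTED-II style compendia).
The screen is a fixed-threshold rule on r, not a p-value procedure; a
two-sided t-approximation p-value is emitted for information only and never
used for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix


@dataclass
class CandidateRecord:
    gene_id: str
    links: list[tuple[str, float]]  # (guide gene, r) for every guide
    n_links_passing: int
    passes: bool

    @property
    def best_r(self) -> float:
        return max(r for _, r in self.links)

    @property
    def best_guide(self) -> str:
        return max(self.links, key=lambda gr: gr[1])[0]


@dataclass
class ScreenResult:
    """Per-candidate correlation links to guide genes and pass/fail calls.

    Candidates are sorted by (links passing desc, best r desc, gene id asc).
    """

    candidates: list[CandidateRecord]
    threshold: float
    min_links: int
    guides: list[str]

    def passing(self) -> list[CandidateRecord]:
        return [c for c in self.candidates if c.passes]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: constant vector has no correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.clip(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)), -1.0, 1.0))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for r under the t-approximation (informational only)."""
    if n < 3:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def screen_candidates(
    matrix: ExpressionMatrix,
    guides: Sequence[str],
    threshold: float = 0.525,
    min_links: int = 2,
) -> ScreenResult:
    """Correlate every non-guide gene against every guide and apply the rule.

    A link "passes" when r > threshold (strictly, positive correlations
    only); a candidate passes when at least ``min_links`` of its guide links
    pass.  Every r is computed on the full sample set.
    """
    guides = list(guides)
    if not guides:
        raise ValueError("no guide genes given")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in guides if g not in index]
    if missing:
        raise ValueError(f"guide genes absent from matrix: {', '.join(missing)}")
    guide_set = set(guides)
    cand_ids = [g for g in matrix.gene_ids if g not in guide_set]
    if not cand_ids:
        raise ValueError("no non-guide genes to screen")

    x = matrix.values
    rows_c = np.array([index[g] for g in cand_ids])
    rows_g = np.array([index[g] for g in guides])
    c = x[rows_c] - x[rows_c].mean(axis=1, keepdims=True)
    g = x[rows_g] - x[rows_g].mean(axis=1, keepdims=True)
    c_sd = np.linalg.norm(c, axis=1)
    g_sd = np.linalg.norm(g, axis=1)
    if (c_sd == 0).any() or (g_sd == 0).any():
        raise ValueError("degenerate input: constant gene profile")
    r = np.clip((c / c_sd[:, None]) @ (g / g_sd[:, None]).T, -1.0, 1.0)

    candidates = []
    for i, gid in enumerate(cand_ids):
        links = [(guides[j], float(r[i, j])) for j in range(len(guides))]
        n_pass = int(np.sum(r[i] > threshold))
        candidates.append(
            CandidateRecord(
                gene_id=gid,
                links=links,
                n_links_passing=n_pass,
                passes=n_pass >= min_links,
            )
        )
    candidates.sort(key=lambda rec: (-rec.n_links_passing, -rec.best_r, rec.gene_id))
    return ScreenResult(
        candidates=candidates, threshold=threshold, min_links=min_links, guides=guides
    )


def write_screen_tsv(
    result: ScreenResult,
    path: str | Path,
    n_samples: int,
    comments: Sequence[str] = (),
) -> None:
    """Write the screen table: one row per candidate with all guide links."""
    with Path(path).open("w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write(
            "gene_id\tn_links_passing\tpasses\tbest_guide\tbest_r\tbest_p\tlinks\n"
        )
        for c in result.candidates:
            link_str = ";".join(f"{g}:{r!r}" for g, r in c.links)
            fh.write(
                f"{c.gene_id}\t{c.n_links_passing}\t{c.passes}\t{c.best_guide}\t"
                f"{c.best_r!r}\t{correlation_p_value(c.best_r, n_samples)!r}\t{link_str}\n"
            )
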