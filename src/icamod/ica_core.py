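"""Fixed-point (fastICA) decomposition of an expression matrix, X = S A.

The genes x samples matrix ``X`` is modelled as a product of a gene
signature matrix ``S`` (genes x k: each gene's weight on every independent
component) and a latent mixing matrix ``A`` (k x samples: each component's
activation across arrays).  The statistical observations are the *samples*:
each array is one draw of an m-dimensional gene-expression vector, and the k
latent activation signals are assumed mutually independent and non-Gaussian
across samples.  This matches how the classic R ``fastICA`` call on a
samples x genes compendium is set up, and it is what makes the signature
rows clusterable: gene loadings are estimated by regression on the
recovered activations and are not re-centered across genes, so shared weak
responses survive into S.

Pipeline: per-gene centering -> PCA whitening to k dimensions (eigendecomposition
of the gene-space covariance, Gram trick when samples < genes) -> symmetric
fixed-point iteration with a logcosh or exp contrast -> unit-variance,
sign-fixed signature columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Relative eigenvalue cutoff for numerical rank detection during whitening.
RANK_EPS = 1e-12


class RankDeficiencyError(ValueError):
    """Requested more components than the matrix numerically supports."""


@dataclass
class ContrastFunction:
    """Non-Gaussianity contrast for the fixed-point iteration.

    ``logcosh`` (g = tanh(alpha u), the negentropy proxy robust for
    super-Gaussian sources) is the default; ``exp`` (g = u exp(-u^2/2))
    weights the tails even less aggressively.
    """

    name: str = "logcosh"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("logcosh", "exp"):
            raise ValueError(f"unknown contrast {self.name!r}")
        if not 1.0 <= self.alpha <= 2.0:
            raise ValueError("alpha must be in [1, 2]")

    def g(self, u: np.ndarray) -> np.ndarray:
        if self.name == "logcosh":
            return np.tanh(self.alpha * u)
        return u * np.exp(-0.5 * u**2)

    def g_prime(self, u: np.ndarray) -> np.ndarray:
        if self.name == "logcosh":
            return self.alpha * (1.0 - np.tanh(self.alpha * u) ** 2)
        return (1.0 - u**2) * np.exp(-0.5 * u**2)


@dataclass
class WhiteningRecord:
    """Everything needed to reproduce the rank-k projection.

    ``components`` holds the top-k eigenvectors of the gene-space covariance
    (genes x k), ``eigenvalues`` their variances, ``gene_means`` the per-gene
    centering offsets and ``transform`` the k x genes whitening map.
    """

    gene_means: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    transform: np.ndarray
    rank: int
    n_samples: int


@dataclass
class ICADecomposition:
    """Result of :func:`fastica`.

    ``S @ A`` plus the restored gene means reproduces the rank-k principal
    projection of the input.  Columns of ``S`` have unit sample variance
    (over genes) and are sign-fixed so the largest-magnitude entry is
    positive.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    S: np.ndarray  # genes x k signature
    A: np.ndarray  # k x samples mixing
    k: int
    whitening: WhiteningRecord
    W: np.ndarray  # k x k orthonormal unmixing (whitened space)
    contrast: ContrastFunction
    converged: bool
    iterations: int
    tolerance_achieved: float
    seed: int


def _as_values(matrix: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def center_and_whiten(
    matrix: ExpressionMatrix | np.ndarray, k: int
) -> tuple[np.ndarray, WhiteningRecord]:
    """Center each gene and whiten the sample observations to k dimensions.

    Samples are treated as observations of an m-dimensional gene variable.
    Returns the k x n_samples whitened data Z with sample covariance
    Z Z^T / n = I, plus the transform record.  Raises
    :class:`RankDeficiencyError` when ``k`` exceeds the numerical rank.
    """
    x = _as_values(matrix)
    m, n = x.shape
    if k < 1:
        raise ValueError("k must be positive")
    if k > min(m, n):
        raise RankDeficiencyError(
            f"k={k} exceeds matrix dimensions {m}x{n} (max {min(m, n)})"
        )
    means = x.mean(axis=1)
    xc = x - means[:, None]
    if m <= n:
        cov = xc @ xc.T / n
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    else:
        # Gram trick: nonzero eigenvalues of (X X^T)/n equal those of (X^T X)/n
        gram = xc.T @ xc / n
        gvals, gvecs = np.linalg.eigh(gram)
        order = np.argsort(gvals)[::-1]
        gvals, gvecs = gvals[order], gvecs[:, order]
        eigvals = gvals
        with np.errstate(invalid="ignore", divide="ignore"):
            eigvecs = xc @ gvecs / np.sqrt(np.maximum(gvals, RANK_EPS) * n)
    eigvals = np.clip(eigvals, 0.0, None)
    rank = int(np.sum(eigvals > max(eigvals[0], 0.0) * RANK_EPS)) if eigvals[0] > 0 else 0
    if k > rank:
        raise RankDeficiencyError(
            f"k={k} exceeds numerical rank {rank} of the centered matrix"
        )
    comp = eigvecs[:, :k]
    vals = eigvals[:k]
    transform = comp.T / np.sqrt(vals)[:, None]  # k x m
    z = transform @ xc  # k x n
    record = WhiteningRecord(
        gene_means=means,
        components=comp,
        eigenvalues=vals,
        transform=transform,
        rank=rank,
        n_samples=n,
    )
    return z, record


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W, the symmetric orthonormalization."""
    s, u = np.linalg.eigh(w @ w.T)
    return (u / np.sqrt(s)) @ u.T @ w


def fastica(
    matrix: ExpressionMatrix,
    k: int = 8,
    contrast: ContrastFunction | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    mode: str = "parallel",
) -> ICADecomposition:
    """Decompose an expression matrix into k independent components.

    Symmetric (parallel) fixed-point extraction by default: the unmixing
    matrix W is initialized from seeded standard normals, orthonormalized,
    and iterated with symmetric decorrelation until the largest rotation of
    any row between iterations falls below ``tol`` (measured as
    max |,|diag(W_new W_old^T)| - 1,|).  ``mode="deflation"`` extracts
    components one at a time with Gram-Schmidt orthogonalization instead.

    Non-convergence is reported via the ``converged`` flag and a warning,
    never an exception.  The run is fully deterministic given ``seed``.
    """
    if contrast is None:
        contrast = ContrastFunction()
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if mode not in ("parallel", "deflation"):
        raise ValueError(f"unknown mode {mode!r}")

    z, record = center_and_whiten(matrix, k)
    n = record.n_samples
    rng = np.random.default_rng(seed)
    w_init = rng.standard_normal((k, k))

    if mode == "parallel":
        w = _sym_decorrelate(w_init)
        lim = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            u = w @ z
            gu = contrast.g(u)
            w_new = gu @ z.T / n - np.diag(contrast.g_prime(u).mean(axis=1)) @ w
            w_new = _sym_decorrelate(w_new)
            lim = float(np.max(np.abs(np.abs(np.diag(w_new @ w.T)) - 1.0)))
            w = w_new
            if lim < tol:
                break
        converged = lim < tol
    else:
        w = np.zeros((k, k))
        lims = []
        for p in range(k):
            wp = w_init[p].copy()
            wp -= w[:p].T @ (w[:p] @ wp)
            wp /= np.linalg.norm(wp)
            lim = np.inf
            for it in range(1, max_iter + 1):
                u = wp @ z
                wp_new = (z * contrast.g(u)).mean(axis=1) - contrast.g_prime(u).mean() * wp
                wp_new -= w[:p].T @ (w[:p] @ wp_new)
                wp_new /= np.linalg.norm(wp_new)
                lim = float(np.abs(np.abs(wp_new @ wp) - 1.0))
                wp = wp_new
                if lim < tol:
                    break
            lims.append(lim)
            w[p] = wp
        lim = max(lims)
        converged = all(l < tol for l in lims)

    if not converged:
        warnings.warn(
            f"fastICA did not converge in {max_iter} iterations "
            f"(last step {lim:.2e} >= tol {tol:.1e})",
            RuntimeWarning,
            stacklevel=2,
        )

    a = w @ z  # k x n estimated activations, unit variance rows
    x = _as_values(matrix)
    xc = x - record.gene_means[:, None]
    s = xc @ a.T / n  # genes x k signature (regression on activations)

    # unit-variance signature columns; scale moves into A
    col_sd = s.std(axis=0, ddof=0)
    col_sd[col_sd == 0] = 1.0
    s = s / col_sd
    a = a * col_sd[:, None]
    # sign convention: largest-magnitude signature entry positive
    flip = np.sign(s[np.argmax(np.abs(s), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    s = s * flip
    a = a * flip[:, None]

    gene_ids = (
        matrix.gene_ids
        if isinstance(matrix, ExpressionMatrix)
        else [f"G{i}" for i in range(x.shape[0])]
    )
    sample_ids = (
        matrix.sample_ids
        if isinstance(matrix, ExpressionMatrix)
        else [f"S{j}" for j in range(x.shape[1])]
    )
    return ICADecomposition(
        gene_ids=list(gene_ids),
        sample_ids=list(sample_ids),
        S=s,
        A=a,
        k=k,
        whitening=record,
        W=w,
        contrast=contrast,
        converged=converged,
        iterations=it,
        tolerance_achieved=lim,
        seed=seed,
    )


def reconstruct(decomposition: ICADecomposition) -> np.ndarray:
    """Return S A plus the restored gene means.

    Equals the rank-k principal projection of the input (the fixed-point
    rotation is orthonormal in the whitened space, so it cannot change the
    projected subspace).
    """
    d = decomposition
    return d.S @ d.A + d.whitening.gene_means[:, None]
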