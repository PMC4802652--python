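"""Principal-component embedding of an expression matrix.

The clustering algorithm in :mod:`pcareduce.hierarchy` works on the score
matrix ``Y`` (cells in the leading ``q`` principal directions) and discards
the trailing, lowest-variance direction after every cluster merge.  This
module provides the expression-matrix container, the PCA projection and the
dimension-dropping bookkeeping.

Conventions
-----------
* Columns (genes) are mean-centered before decomposition; variance scaling
  is available but off by default, so genes keep their relative variance.
* The decomposition is a singular value decomposition of the centered
  matrix, which is numerically stabler than an eigendecomposition of the
  d x d covariance when there are far more genes than cells.
* Component signs are fixed deterministically: the largest-magnitude gene
  loading of each component is made positive, so repeated runs are
  bit-identical across platforms.
* Explained variances use the n-1 (sample) denominator, matching the
  sample-moment arithmetic used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CannotReduceError, InvalidInputError, InvalidParameterError

__all__ = ["ExpressionMatrix", "ScoreMatrix", "compute_scores", "drop_trailing_direction"]


@dataclass
class ExpressionMatrix:
    """An n cells x d genes matrix of real-valued expression.

    Values are arbitrary real numbers, typically log-transformed counts.
    Cells are rows.  Identifiers must be unique and the matrix must be
    finite with at least two cells and two genes.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("expression matrix must be two-dimensional")
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise InvalidInputError(f"need at least 2 cells and 2 genes, got {n} x {d}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InvalidInputError(
                f"non-finite value at cell index {bad[0]}, gene index {bad[1]}"
            )
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{j}" for j in range(d)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n:
            raise InvalidInputError("cell_ids length does not match row count")
        if len(self.gene_ids) != d:
            raise InvalidInputError("gene_ids length does not match column count")
        if len(set(self.cell_ids)) != n:
            raise InvalidInputError("cell_ids are not unique")
        if len(set(self.gene_ids)) != d:
            raise InvalidInputError("gene_ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ScoreMatrix:
    """Cells projected onto the leading q principal directions.

    ``scores`` has one column per direction, ordered by decreasing
    ``explained_variance`` (sample variance of the column).  Columns are
    centered by construction.
    """

    scores: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.scores.ndim != 2:
            raise InvalidInputError("scores must be two-dimensional")
        if self.explained_variance.shape != (self.scores.shape[1],):
            raise InvalidInputError("one explained variance per score column required")
        if np.any(np.diff(self.explained_variance) > 1e-9 * max(1.0, self.explained_variance[0] if self.explained_variance.size else 1.0)):
            raise InvalidInputError("explained_variance must be non-increasing")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def q(self) -> int:
        return self.scores.shape[1]


def compute_scores(X: ExpressionMatrix, q: int, scale: bool = False) -> ScoreMatrix:
    """Project cells onto the first ``q`` principal directions.

    Parameters
    ----------
    X
        Expression matrix, cells as rows.
    q
        Number of leading directions to keep; must satisfy
        ``1 <= q <= min(n - 1, d)``.
    scale
        If True, divide each centered gene column by its sample standard
        deviation before decomposition (constant genes are left as zeros).
        Off by default.

    Returns
    -------
    ScoreMatrix
        Centered scores with per-column sample variances, deterministic in
        sign (largest-magnitude loading of each component forced positive).
    """
    n, d = X.values.shape
    q_max = min(n - 1, d)
    if not (isinstance(q, (int, np.integer)) and 1 <= q <= q_max):
        raise InvalidParameterError(f"q must be an integer in [1, {q_max}], got {q!r}")
    centered = X.values - X.values.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centered = centered / sd
    # SVD of the centered matrix; scores are U * S, loadings the rows of Vt.
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    # Deterministic sign: make the largest-|loading| entry of each component positive.
    lead = np.argmax(np.abs(Vt), axis=1)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), lead])
    signs[signs == 0] = 1.0
    U = U * signs
    scores = U[:, :q] * S[:q]
    explained = S[:q] ** 2 / (n - 1)
    return ScoreMatrix(scores=scores, explained_variance=explained)


def drop_trailing_direction(Y: ScoreMatrix) -> ScoreMatrix:
    """Remove the last (lowest-variance) score column.

    This is the per-merge reduction step: after two clusters unite at the
    k-cluster level, the working subspace shrinks from k-1 to k-2
    dimensions by discarding the principal direction that explains the
    least variance.
    """
    if Y.q < 2:
        raise CannotReduceError("cannot drop a direction from a 1-D score matrix")
    return ScoreMatrix(
        scores=Y.scores[:, :-1].copy(),
        explained_variance=Y.explained_variance[:-1].copy(),
    )
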