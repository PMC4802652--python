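"""Partition agreement and consensus clustering across stochastic runs.

Agreement between a hierarchy level and a set of reference labels is
measured with the Hubert–Arabie Adjusted Rand Index (ARANDI): 1 for
identical partitions up to relabelling, around 0 for independent ones.
Repeated sampling runs are combined through a co-association (consensus)
matrix — the fraction of runs in which each pair of cells shares a
cluster — which is then cut by average-linkage agglomeration on
``1 - co_association``.  The co-association construction is the most
common ensemble-clustering scheme; it is a reasonable default, not the
only possible one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .errors import InvalidInputError, InvalidParameterError
from .hierarchy import Hierarchy

__all__ = [
    "ConsensusMatrix",
    "adjusted_rand_index",
    "level_concordance",
    "build_consensus",
    "build_consensus_from_labels",
    "cut_consensus",
]


@dataclass
class ConsensusMatrix:
    """n x n co-association frequencies over ``n_runs`` partitions.

    Entry (a, b) is the fraction of runs in which cells a and b were
    assigned to the same cluster; the diagonal is identically 1.
    """

    co_assoc: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        self.co_assoc = np.asarray(self.co_assoc, dtype=float)
        m = self.co_assoc
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("co-association matrix must be square")
        if not np.allclose(m, m.T):
            raise InvalidInputError("co-association matrix must be symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise InvalidInputError("co-association entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.co_assoc.shape[0]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Symmetric, invariant to relabelling, 1.0 iff the partitions coincide
    up to renaming, and 0 in expectation under the permutation model
    (hence exactly 0 against the all-in-one-cluster partition).
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or labels_a.ndim != 1:
        raise InvalidInputError("partitions must be 1-D and of equal length")
    if labels_a.shape[0] < 2:
        raise InvalidInputError("need at least two cells")
    return float(adjusted_rand_score(labels_a, labels_b))


def level_concordance(h: Hierarchy, refs: list[tuple[str, np.ndarray]]) -> pd.DataFrame:
    """ARANDI of every hierarchy level against every reference labelling.

    Returns a tidy table with columns ``level``, ``reference`` and
    ``arandi`` — one row per (level, reference) combination — from which
    the level maximising agreement with each reference can be read off.
    """
    records = []
    for name, labels in refs:
        labels = np.asarray(labels)
        if labels.shape[0] != h.n:
            raise InvalidInputError(
                f"reference {name!r} has {labels.shape[0]} labels for {h.n} cells"
            )
        for level in sorted(h.levels):
            records.append(
                {
                    "level": level,
                    "reference": name,
                    "arandi": adjusted_rand_index(h.levels[level], labels),
                }
            )
    return pd.DataFrame.from_records(records, columns=["level", "reference", "arandi"])


def build_consensus_from_labels(partitions: list[np.ndarray]) -> ConsensusMatrix:
    """Co-association matrix from a list of equal-length label vectors."""
    if not partitions:
        raise InvalidInputError("need at least one partition")
    n = len(partitions[0])
    co = np.zeros((n, n))
    for labels in partitions:
        labels = np.asarray(labels)
        if labels.shape != (n,):
            raise InvalidInputError("partitions must all have the same length")
        co += (labels[:, None] == labels[None, :]).astype(float)
    return ConsensusMatrix(co_assoc=co / len(partitions), n_runs=len(partitions))


def build_consensus(hierarchies: list[Hierarchy], level: int) -> ConsensusMatrix:
    """Co-association frequencies at one hierarchy level across runs."""
    if not hierarchies:
        raise InvalidInputError("need at least one hierarchy")
    n = hierarchies[0].n
    parts = []
    for h in hierarchies:
        if h.n != n:
            raise InvalidInputError("hierarchies cover different numbers of cells")
        if level not in h.levels:
            raise InvalidParameterError(f"level {level} absent from a hierarchy")
        parts.append(h.levels[level])
    return build_consensus_from_labels(parts)


def cut_consensus(cm: ConsensusMatrix, k: int) -> np.ndarray:
    """Average-linkage consensus partition into ``k`` clusters.

    Agglomerates on the distance ``1 - co_association`` and cuts the
    dendrogram at ``k`` clusters; labels are 1-based.
    """
    n = cm.n
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= n):
        raise InvalidParameterError(f"k must be an integer in [1, {n}], got {k!r}")
    if k == n:
        return np.arange(1, n + 1)
    dist = 1.0 - cm.co_assoc
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=int(k), criterion="maxclust")
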