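"""The pcaReduce agglomerative clustering algorithm.

Starting from a K-means partition of the cells in the leading ``K - 1``
principal directions, the algorithm repeatedly (1) scores every pair of
clusters by the likelihood that their members form a single Gaussian
cluster with size-weighted pooled moments, (2) merges one pair — either
the most probable pair or a pair sampled in proportion to the normalised
merge probabilities — and (3) discards the trailing principal direction,
so that a partition into k clusters always lives in a k-1 dimensional
subspace.  The result is a nested hierarchy of partitions from K clusters
down to one, each level tied to its own reduced representation of the
data.

Pooled moments of a candidate merge of clusters i and j are the
size-weighted convex combinations

    mu_ij    = n_i/(n_i+n_j) mu_i    + n_j/(n_i+n_j) mu_j
    Sigma_ij = n_i/(n_i+n_j) Sigma_i + n_j/(n_i+n_j) Sigma_j

and the merge score is, by default, the joint log-likelihood of all member
points of both clusters under the Gaussian N(mu_ij, Sigma_ij).  Note that
a joint product of densities mechanically favours merging *small* clusters
(fewer factors); ``score_mode="mean"`` divides by the member count and is
provided as a documented alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from sklearn.cluster import KMeans

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NumericalDegeneracyError,
    StaleCandidateError,
)
from .pca import ExpressionMatrix, ScoreMatrix, compute_scores, drop_trailing_direction

__all__ = [
    "ClusterState",
    "MergeCandidate",
    "Hierarchy",
    "initialise",
    "pooled_moments",
    "merge_log_score",
    "score_all_pairs",
    "select_merge",
    "apply_merge",
    "run",
    "run_ensemble",
]

_LOG_2PI = np.log(2.0 * np.pi)

#: Default ridge scale: epsilon = RIDGE_SCALE * mean diagonal of the global
#: score covariance, floored at RIDGE_FLOOR, added to pooled covariances
#: before inversion.  Keeps singleton (zero) covariances invertible.
RIDGE_SCALE = 1e-6
RIDGE_FLOOR = 1e-10

#: K-means restarts and bounded retries on an empty cluster.
KMEANS_RESTARTS = 10
EMPTY_CLUSTER_RETRIES = 5


@dataclass
class ClusterState:
    """One level of the hierarchy: a partition plus per-cluster moments.

    ``assignment`` holds 0-based cluster indices; ``centroids[i]`` and
    ``covariances[i]`` are the mean and covariance of cluster i in the
    *current* q_cur-dimensional score subspace.  Covariances use the
    maximum-likelihood (1/n_i) denominator so singletons yield the zero
    matrix.
    """

    assignment: np.ndarray
    sizes: np.ndarray
    centroids: np.ndarray
    covariances: np.ndarray
    q_cur: int

    @property
    def k(self) -> int:
        return len(self.sizes)

    @property
    def n(self) -> int:
        return len(self.assignment)


@dataclass
class MergeCandidate:
    """A scored proposal to unite clusters ``pair = (i, j)``, i < j."""

    pair: tuple[int, int]
    pooled_mean: np.ndarray
    pooled_cov: np.ndarray
    log_score: float
    k_at_scoring: int  # number of clusters when scored; guards staleness


@dataclass
class Hierarchy:
    """Full output of one run: nested partitions plus the merge trace.

    ``levels[k]`` is the partition into k clusters, labels canonicalised to
    1..k by order of first appearance so comparisons are label-invariant.
    ``merge_trace`` records, per merge, the cluster count before the merge,
    the merged pair (canonical labels), the log merge score and the working
    dimension at scoring time.
    """

    levels: dict[int, np.ndarray]
    merge_trace: list[dict]
    strategy: str
    seed: int
    k_init: int
    kmeans_seed: int
    cell_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.levels[1])


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict[int, int] = {}
    for idx, lab in enumerate(labels):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[idx] = mapping[lab]
    return out


def _ml_cov(rows: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Sample covariance with the maximum-likelihood 1/n denominator."""
    diff = rows - mean
    return diff.T @ diff / rows.shape[0]


def _moments_from_assignment(
    Y: np.ndarray, assignment: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sizes = np.zeros(k, dtype=int)
    q = Y.shape[1]
    centroids = np.zeros((k, q))
    covariances = np.zeros((k, q, q))
    for i in range(k):
        rows = Y[assignment == i]
        if rows.shape[0] == 0:
            raise InvalidInputError(f"cluster {i} is empty")
        sizes[i] = rows.shape[0]
        centroids[i] = rows.mean(axis=0)
        covariances[i] = _ml_cov(rows, centroids[i])
    return sizes, centroids, covariances


def default_ridge(Y: ScoreMatrix) -> float:
    """Ridge epsilon derived from the global score covariance diagonal."""
    global_var = Y.scores.var(axis=0, ddof=0)
    return max(RIDGE_SCALE * float(global_var.mean()), RIDGE_FLOOR)


def state_from_assignment(Y: ScoreMatrix, assignment: np.ndarray) -> ClusterState:
    """Build a ClusterState (moments recomputed from members) from labels.

    Labels may be arbitrary hashables; they are mapped to 0..k-1 by first
    appearance.  Every cluster must be non-empty by construction.
    """
    assignment = np.asarray(assignment)
    if assignment.shape != (Y.n,):
        raise InvalidInputError("assignment length must match the number of cells")
    canon = _canonical(assignment) - 1
    k = canon.max() + 1
    sizes, centroids, covariances = _moments_from_assignment(Y.scores, canon, k)
    return ClusterState(
        assignment=canon, sizes=sizes, centroids=centroids,
        covariances=covariances, q_cur=Y.q,
    )


def initialise(Y: ScoreMatrix, K: int, seed: int) -> ClusterState:
    """K-means initialisation of the hierarchy on the score matrix.

    Runs K-means with ``KMEANS_RESTARTS`` restarts keeping the best
    inertia.  If a run returns an empty cluster (possible with heavily
    duplicated points), it is retried with a fresh sub-seed up to
    ``EMPTY_CLUSTER_RETRIES`` times before raising.
    """
    n = Y.n
    if not (isinstance(K, (int, np.integer)) and 2 <= K <= n):
        raise InvalidParameterError(f"K must be an integer in [2, {n}], got {K!r}")
    rng = np.random.default_rng(seed)
    for _ in range(EMPTY_CLUSTER_RETRIES + 1):
        km_seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=int(K), n_init=KMEANS_RESTARTS, random_state=km_seed)
        labels = km.fit_predict(Y.scores)
        if len(np.unique(labels)) == int(K):
            return state_from_assignment(Y, labels)
    raise NumericalDegeneracyError(
        f"K-means produced an empty cluster in {EMPTY_CLUSTER_RETRIES + 1} attempts"
    )


def pooled_moments(
    size_i: int,
    mean_i: np.ndarray,
    cov_i: np.ndarray,
    size_j: int,
    mean_j: np.ndarray,
    cov_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Size-weighted convex combination of two clusters' means and covariances."""
    mean_i = np.asarray(mean_i, dtype=float)
    mean_j = np.asarray(mean_j, dtype=float)
    cov_i = np.asarray(cov_i, dtype=float)
    cov_j = np.asarray(cov_j, dtype=float)
    if size_i < 1 or size_j < 1:
        raise InvalidInputError("cluster sizes must be at least 1")
    if mean_i.shape != mean_j.shape or cov_i.shape != cov_j.shape:
        raise InvalidInputError("moment shapes do not agree")
    q = mean_i.shape[0]
    if cov_i.shape != (q, q):
        raise InvalidInputError("covariance shape does not match mean dimension")
    w_i = size_i / (size_i + size_j)
    w_j = size_j / (size_i + size_j)
    return w_i * mean_i + w_j * mean_j, w_i * cov_i + w_j * cov_j


def merge_log_score(
    members: np.ndarray,
    pooled_mean: np.ndarray,
    pooled_cov: np.ndarray,
    ridge: float = 0.0,
    mode: str = "joint",
) -> float:
    """Log-likelihood of member points under the pooled Gaussian.

    Parameters
    ----------
    members
        m x q array of score rows belonging to the union of the two
        clusters.
    pooled_mean, pooled_cov
        The merged cluster's moments.
    ridge
        Nonnegative value added to the covariance diagonal before the
        Cholesky factorisation.
    mode
        ``"joint"`` (default) returns the sum of per-point log densities;
        ``"mean"`` returns the average, removing the size dependence of
        the joint product.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if members.shape[0] < 1:
        raise InvalidInputError("need at least one member point")
    q = members.shape[1]
    cov = np.asarray(pooled_cov, dtype=float) + ridge * np.eye(q)
    try:
        factor = cho_factor(cov, lower=True)
    except LinAlgError as exc:
        raise NumericalDegeneracyError(
            f"pooled covariance not positive definite (ridge={ridge:g})"
        ) from exc
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    diff = members - np.asarray(pooled_mean, dtype=float)
    maha = np.einsum("ij,ij->i", diff, cho_solve(factor, diff.T).T)
    logps = -0.5 * (q * _LOG_2PI + logdet + maha)
    if mode == "joint":
        return float(logps.sum())
    if mode == "mean":
        return float(logps.mean())
    raise InvalidParameterError(f"unknown score mode {mode!r}")


def score_all_pairs(
    state: ClusterState,
    Y: ScoreMatrix,
    ridge: float = 0.0,
    mode: str = "joint",
) -> list[MergeCandidate]:
    """Score every unordered pair of live clusters as a merge candidate."""
    k = state.k
    if k < 2:
        raise InvalidParameterError("need at least two clusters to score merges")
    candidates = []
    for i in range(k):
        rows_i = Y.scores[state.assignment == i]
        for j in range(i + 1, k):
            mean, cov = pooled_moments(
                state.sizes[i], state.centroids[i], state.covariances[i],
                state.sizes[j], state.centroids[j], state.covariances[j],
            )
            members = np.vstack([rows_i, Y.scores[state.assignment == j]])
            try:
                score = merge_log_score(members, mean, cov, ridge=ridge, mode=mode)
            except NumericalDegeneracyError as exc:
                raise NumericalDegeneracyError(
                    f"degenerate pooled covariance for cluster pair ({i}, {j}): {exc}"
                ) from exc
            candidates.append(
                MergeCandidate(pair=(i, j), pooled_mean=mean, pooled_cov=cov,
                               log_score=score, k_at_scoring=k)
            )
    return candidates


def select_merge(
    candidates: list[MergeCandidate],
    strategy: str,
    rng: np.random.Generator | None = None,
) -> MergeCandidate:
    """Choose the merge to perform.

    ``"max"`` picks the highest log score, breaking exact ties by the
    lexicographically smallest pair.  ``"sample"`` draws a candidate with
    probability proportional to exp(log_score - max log_score) — the
    normalised merge probabilities, computed stably in log space.
    """
    if not candidates:
        raise InvalidInputError("no merge candidates")
    if strategy == "max":
        return min(candidates, key=lambda c: (-c.log_score, c.pair))
    if strategy == "sample":
        if rng is None:
            raise InvalidParameterError("sampling strategy requires an rng")
        scores = np.array([c.log_score for c in candidates])
        weights = np.exp(scores - scores.max())
        probs = weights / weights.sum()
        return candidates[int(rng.choice(len(candidates), p=probs))]
    raise InvalidParameterError(f"unknown strategy {strategy!r}")


def apply_merge(
    state: ClusterState, chosen: MergeCandidate, Y: ScoreMatrix
) -> tuple[ClusterState, ScoreMatrix]:
    """Unite the chosen pair and drop the trailing principal direction.

    The merged cluster takes the pooled moments (restricted to surviving
    dimensions); all other clusters keep their moments minus the last
    coordinate.  The final merge down to one cluster happens in 1-D and
    performs no further dimension drop.
    """
    i, j = chosen.pair
    k = state.k
    if chosen.k_at_scoring != k or not (0 <= i < j < k):
        raise StaleCandidateError(
            f"candidate pair ({i}, {j}) scored at k={chosen.k_at_scoring} "
            f"does not match current state with k={k}"
        )
    drop_dim = state.q_cur >= 2 and k > 2
    sl = slice(0, state.q_cur - 1) if drop_dim else slice(0, state.q_cur)

    assignment = state.assignment.copy()
    assignment[assignment == j] = i
    assignment[assignment > j] = assignment[assignment > j] - 1

    keep = [c for c in range(k) if c != j]
    sizes = state.sizes[keep].copy()
    centroids = state.centroids[keep][:, sl].copy()
    covariances = state.covariances[keep][:, sl, sl].copy()
    sizes[i] = state.sizes[i] + state.sizes[j]
    centroids[i] = chosen.pooled_mean[sl]
    covariances[i] = chosen.pooled_cov[sl, sl]

    Y_new = drop_trailing_direction(Y) if drop_dim else Y
    new_state = ClusterState(
        assignment=assignment, sizes=sizes, centroids=centroids,
        covariances=covariances, q_cur=Y_new.q,
    )
    return new_state, Y_new


def run(
    X: ExpressionMatrix,
    k_init: int = 31,
    strategy: str = "max",
    seed: int = 0,
    *,
    scale: bool = False,
    ridge: float | None = None,
    score_mode: str = "joint",
    initial_assignment: np.ndarray | None = None,
) -> Hierarchy:
    """Run the full agglomeration from ``k_init`` clusters down to one.

    The data are projected onto the leading ``k_init - 1`` principal
    directions, partitioned by K-means (or by ``initial_assignment`` if
    given, which must contain exactly ``k_init`` non-empty clusters), and
    merged one pair at a time, losing one principal direction per merge.
    The default ``k_init=31`` (30 leading directions) follows the standard
    configuration for datasets with a few hundred cells.

    The same ``seed`` always produces an identical Hierarchy; the master
    seed is split into independent sub-streams for the K-means
    initialisation and the sampling strategy.
    """
    n, d = X.values.shape
    if not (isinstance(k_init, (int, np.integer)) and 2 <= k_init <= min(n, d + 1)):
        raise InvalidParameterError(
            f"k_init must be an integer in [2, {min(n, d + 1)}], got {k_init!r}"
        )
    if strategy not in ("max", "sample"):
        raise InvalidParameterError(f"unknown strategy {strategy!r}")
    k_init = int(k_init)
    seed = int(seed)
    ss = np.random.SeedSequence(seed)
    kmeans_ss, sample_ss = ss.spawn(2)
    kmeans_seed = int(kmeans_ss.generate_state(1)[0] & 0x7FFFFFFF)
    sample_rng = np.random.default_rng(sample_ss)

    Y = compute_scores(X, k_init - 1, scale=scale)
    if ridge is None:
        ridge = default_ridge(Y)
    if initial_assignment is not None:
        state = state_from_assignment(Y, np.asarray(initial_assignment))
        if state.k != k_init:
            raise InvalidParameterError(
                f"initial_assignment has {state.k} clusters, expected {k_init}"
            )
    else:
        state = initialise(Y, k_init, kmeans_seed)

    levels = {k_init: _canonical(state.assignment)}
    trace: list[dict] = []
    for k in range(k_init, 1, -1):
        candidates = score_all_pairs(state, Y, ridge=ridge, mode=score_mode)
        chosen = select_merge(candidates, strategy, rng=sample_rng)
        trace.append(
            {
                "level": k,
                "cluster_a": int(chosen.pair[0]) + 1,
                "cluster_b": int(chosen.pair[1]) + 1,
                "log_score": float(chosen.log_score),
                "dim": Y.q,
            }
        )
        state, Y = apply_merge(state, chosen, Y)
        levels[k - 1] = _canonical(state.assignment)
    return Hierarchy(
        levels=levels, merge_trace=trace, strategy=strategy, seed=seed,
        k_init=k_init, kmeans_seed=kmeans_seed, cell_ids=list(X.cell_ids),
    )


def run_ensemble(
    X: ExpressionMatrix,
    k_init: int = 31,
    n_runs: int = 100,
    seed: int = 0,
    **kwargs,
) -> list[Hierarchy]:
    """Repeated sampling-strategy runs with sub-seeds split from ``seed``.

    Stochasticity enters through both the K-means initialisation and the
    probabilistic merge choices, so the ensemble explores alternative
    hierarchies; it is the input to consensus clustering.  The default of
    100 runs matches common consensus practice for a few hundred cells.
    """
    if not (isinstance(n_runs, (int, np.integer)) and n_runs >= 1):
        raise InvalidParameterError(f"n_runs must be a positive integer, got {n_runs!r}")
    sub_seeds = [
        int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for child in np.random.SeedSequence(int(seed)).spawn(int(n_runs))
    ]
    return [run(X, k_init, "sample", s, **kwargs) for s in sub_seeds]
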