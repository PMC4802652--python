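# Methods

## Model and procedure

The algorithm couples agglomerative clustering with principal-component
analysis so that the number of clusters and the dimensionality of the
representation decrease together. Clustering starts from a K-means
partition of the cells in the leading K − 1 principal directions of the
column-centered expression matrix. At each step, every unordered pair of
clusters (i, j) is scored by how plausible their union is as a *single*
Gaussian cluster: the candidate cluster's moments are the size-weighted
convex combinations

    μ_ij = w_i μ_i + w_j μ_j,   Σ_ij = w_i Σ_i + w_j Σ_j,   w_i = n_i/(n_i+n_j)

and the score is the joint log-likelihood of all member cells of both
clusters under N(μ_ij, Σ_ij). One pair is merged — the best pair
(`strategy="max"`) or a pair drawn in proportion to the normalised merge
probabilities (`strategy="sample"`) — and the trailing, lowest-variance
principal direction is discarded, so a k-cluster partition is always
scored in a (k − 1)-dimensional subspace. Iterating to a single cluster
yields K nested partitions.

The modelling assumptions are: clusters are approximately Gaussian in the
score space; broad classes separate in high-variance principal directions
while fine subtypes need additional, lower-variance directions; and the
pooled (moment-averaged) Gaussian is an adequate description of a
candidate union. Note that Σ_ij averages the two covariances and does
*not* include the between-centroid spread, so a union of two well-separated
clusters is heavily penalised through the likelihood of its members — this
is what makes the score useful for agglomeration.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `k_init` | 31 | initial cluster count; clustering starts in `k_init − 1` PCs. 31 (30 directions) is the conventional choice for a few hundred cells; the benchmark study uses 12 because it has 9 true subtypes. |
| `strategy` | `sample` (CLI), `max` (library) | merge selection rule; `max` is deterministic given the init, `sample` explores alternative hierarchies. |
| `n_runs` | 100 | sampling runs for ensembles/consensus. |
| `scale` | off | optionally scale genes to unit variance before PCA. Centering-only is the default so genes keep their relative variance. |
| `ridge` | 1e−6 × mean diagonal of the global score covariance (floor 1e−10) | added to pooled covariance diagonals before inversion; keeps singleton and rank-deficient clusters scoreable. Units: score variance. |
| `score_mode` | `joint` | `joint` sums per-cell log densities; `mean` averages them. |

## Design choices where the design was open

**Merge score.** The merge probability of a pair is operationalised as
the joint log-likelihood of the union's members under the pooled Gaussian
(a product of per-cell densities, computed in log space). A joint product
mechanically favours merging small clusters — fewer factors — so the
per-cell mean log-likelihood is exposed as `score_mode="mean"`; the joint
form remains the default. Sampling weights are formed as
exp(log score − max log score), normalised over candidates (log-sum-exp),
to avoid underflow. Other readings of the merge probability (density of
the pooled centroid, Bayes-factor-style quantities) are possible; none is
claimed to be canonical.

**Moment propagation.** After a merge the united cluster carries the
pooled moments forward, restricted to the surviving dimensions, rather
than recomputing moments from its member cells. The pooled covariance
under-states the spread of a union of separated clusters (see above),
which in practice biases later merges *away* from chaining through such
unions; recomputation from members is the documented alternative and
would require one extra pass over the members per merge.

**Covariance estimation and regularisation.** Per-cluster covariances use
the maximum-likelihood 1/n_i denominator so singletons yield a zero
matrix, which the ridge term then makes invertible. The ridge scales with
the global score variance so its effect is comparable across datasets; if
a pooled covariance is still not positive definite the offending pair is
named in the raised error rather than silently inflated further.

**Numerical determinism.** PCA is an SVD of the centered matrix with a
fixed sign convention (largest-magnitude gene loading of each component
positive), K-means uses 10 restarts keeping the best inertia with bounded
retries on an empty cluster, exact ties in `max` selection break to the
lexicographically smallest pair, and emitted labels are canonicalised by
first appearance. A master seed is split into independent sub-streams
(K-means, sampling; per-run sub-seeds for ensembles) via a counter-based
splitting scheme, and each run's seeds are recorded in its metadata, so
identical seeds give bit-identical outputs.

**Dimension schedule boundary.** The final merge (2 → 1 clusters) is
scored in one dimension and performs no further drop; one dimension is the
floor.

**Consensus.** Ensembles are combined per hierarchy level through the
co-association matrix (fraction of runs placing each cell pair together),
clustered by average linkage on 1 − co-association and cut at the
requested cluster count. This is the most common ensemble-clustering
construction, chosen as a reasonable default rather than as the only
defensible one; combining levels jointly across whole hierarchies is a
possible extension.

## The synthetic benchmark

The generator draws fine-cluster means hierarchically: coarse class means
on a few leading latent axes, fine within-class offsets on further axes,
both rescaled so the *minimum* pairwise distance equals the requested
separation (in units of the within-cluster standard deviation). The latent
signal is embedded into gene space by a random orthonormal map (distances
preserved), isotropic Gaussian noise is added, and entries are optionally
zeroed at a dropout rate. Giving coarse offsets larger magnitude than fine
ones places the broad structure in the high-variance directions by
construction rather than by post-hoc rotation.

The fixed default benchmark has 4 coarse classes, one of which splits into
three subtypes (9 fine clusters), 30 cells per subtype (270 cells), 500
genes, separations 10 (coarse) and 6 (fine) within-cluster SDs on 3 + 6
latent axes, unit noise and no dropout — deliberately solvable, so that
failures indicate algorithmic defects rather than an impossible instance.
These sizes also keep the full test suite and the acceptance study at
desk scale (a complete 20-run study takes a few seconds).

What the generator does **not** emulate: count distributions, library-size
and batch effects, gene–gene correlation beyond the low-rank signal,
realistic gene counts (thousands), or dropout that depends on expression
level. Passing tests on this benchmark therefore demonstrate the
machinery — nested partitions, dimension schedule, recovery of planted
two-level structure, consensus behaviour — not performance on real
single-cell data, where separability assumptions may fail.

## Degenerate inputs and edge cases

Non-finite matrices, duplicate identifiers and out-of-range parameters are
rejected up front with positional context. Constant matrices give all-zero
scores (and K-means then fails to produce K distinct clusters, which is
reported after bounded retries). `k_init = n` starts from singletons whose
covariances are zero matrices, handled by the ridge. Matrix Market inputs
are densified on read: the merge arithmetic is dense in at most
`k_init − 1` dimensions regardless of input sparsity.

## Known limitations

* The joint merge score depends on cluster sizes; hierarchies obtained
  under `joint` and `mean` modes can differ, and no claim is made that
  either matches any particular historical implementation.
* Consensus quality degrades when runs disagree on cluster *counts* at the
  combined level in heterogeneous ways; the co-association matrix only
  sees co-membership.
* No automatic selection of the "true" number of clusters is attempted —
  the hierarchy reports every level and the user (or a reference labelling
  via `evaluate`) decides which levels are interpretable.
* No gene filtering or normalisation is performed; inputs are taken as
  given.
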