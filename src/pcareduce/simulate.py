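"""Synthetic expression matrices with a two-level cluster hierarchy.

The generator emulates the study design the clustering algorithm targets:
a handful of broad cell classes (e.g. tissues), each split into finer
subtypes (e.g. cell lines), where the broad separation is carried by a few
high-variance latent directions and the subtype separation by additional,
lower-variance directions.  After projection onto principal components the
coarse structure therefore dominates the leading directions while the fine
structure only becomes resolvable in higher-dimensional representations —
exactly the regime in which per-merge dimension reduction is expected to
recover both levels.

The model is Gaussian on a log-expression-like scale: cluster means live
in a low-dimensional latent space, are embedded into gene space by a
random orthonormal map (so latent distances are preserved), and isotropic
Gaussian noise plus optional dropout (zeroing) is applied per entry.  It
makes no attempt to match count distributions, library-size effects or
real gene-level statistics; it provides known two-layer ground truth with
controllable effect sizes, nothing more.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .pca import ExpressionMatrix

__all__ = ["HierarchySpec", "generate", "default_benchmark", "DEFAULT_BENCHMARK_SPEC"]


@dataclass
class HierarchySpec:
    """Parameters of the two-level hierarchical mixture.

    Separations are *minimum* distances between class means in units of
    the within-cluster standard deviation (``noise_sd``): random mean
    placements are rescaled so the closest pair of coarse means is exactly
    ``coarse_separation * noise_sd`` apart, and likewise the closest pair
    of sibling fine offsets.  ``coarse_separation > fine_separation``
    encodes the premise that broad classes are easier to separate than
    subtypes.
    """

    coarse_k: int = 4
    fine_per_coarse: int | Sequence[int] = 2
    n_per_fine: int = 30
    d: int = 500
    coarse_separation: float = 10.0
    fine_separation: float = 6.0
    coarse_dims: int = 3
    fine_dims: int = 6
    noise_sd: float = 1.0
    dropout_rate: float = 0.0
    seed: int = 0

    def fine_counts(self) -> list[int]:
        if isinstance(self.fine_per_coarse, (int, np.integer)):
            return [int(self.fine_per_coarse)] * self.coarse_k
        counts = [int(c) for c in self.fine_per_coarse]
        if len(counts) != self.coarse_k:
            raise InvalidParameterError(
                "fine_per_coarse sequence length must equal coarse_k"
            )
        return counts

    def validate(self) -> None:
        counts = self.fine_counts()
        if self.coarse_k < 1 or any(c < 1 for c in counts) or self.n_per_fine < 1:
            raise InvalidParameterError("all class counts must be positive")
        if self.d < 2 or self.coarse_dims < 1 or self.fine_dims < 1:
            raise InvalidParameterError("dimension counts must be positive (d >= 2)")
        if self.coarse_dims + self.fine_dims > self.d:
            raise InvalidParameterError("latent dimensions exceed number of genes")
        if not (self.coarse_separation > self.fine_separation > 0):
            raise InvalidParameterError(
                "require coarse_separation > fine_separation > 0"
            )
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be positive")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise InvalidParameterError("dropout_rate must lie in [0, 1]")

    def to_dict(self) -> dict:
        out = asdict(self)
        if not isinstance(out["fine_per_coarse"], int):
            out["fine_per_coarse"] = list(out["fine_per_coarse"])
        return out


def _spread_points(rng: np.random.Generator, m: int, dims: int, min_dist: float) -> np.ndarray:
    """m centered random points rescaled so the closest pair is min_dist apart."""
    if m == 1:
        return np.zeros((1, dims))
    pts = rng.standard_normal((m, dims))
    pts -= pts.mean(axis=0)
    dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    closest = dists[np.triu_indices(m, k=1)].min()
    if closest == 0.0:  # astronomically unlikely; resample deterministically
        return _spread_points(rng, m, dims, min_dist)
    return pts * (min_dist / closest)


def generate(
    spec: HierarchySpec, return_means: bool = False
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray] | tuple[
    ExpressionMatrix, np.ndarray, np.ndarray, np.ndarray
]:
    """Draw one matrix plus its coarse and fine ground-truth labels.

    Returns ``(X, coarse, fine)`` where the coarse label is a deterministic
    function of the fine label.  Identical specs (including seed) give
    bit-identical outputs.  With ``return_means=True`` the gene-space
    generating mean of each fine cluster (row per fine label) is appended,
    which is useful for checking generator calibration.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = spec.fine_counts()
    latent_dim = spec.coarse_dims + spec.fine_dims

    coarse_means = _spread_points(
        rng, spec.coarse_k, spec.coarse_dims,
        spec.coarse_separation * spec.noise_sd,
    )
    fine_means, coarse_of_fine = [], []
    for c, m_c in enumerate(counts):
        offsets = _spread_points(
            rng, m_c, spec.fine_dims, spec.fine_separation * spec.noise_sd
        )
        for o in offsets:
            fine_means.append(np.concatenate([coarse_means[c], o]))
            coarse_of_fine.append(c)
    fine_means = np.asarray(fine_means)

    n_fine = len(fine_means)
    n = n_fine * spec.n_per_fine
    fine = np.repeat(np.arange(1, n_fine + 1), spec.n_per_fine)
    coarse = np.asarray(coarse_of_fine)[fine - 1] + 1
    latent = fine_means[fine - 1]

    # Random orthonormal embedding: latent distances preserved in gene space.
    basis, _ = np.linalg.qr(rng.standard_normal((spec.d, latent_dim)))
    values = latent @ basis.T + spec.noise_sd * rng.standard_normal((n, spec.d))
    if spec.dropout_rate > 0:
        values[rng.random((n, spec.d)) < spec.dropout_rate] = 0.0

    X = ExpressionMatrix(
        values=values,
        cell_ids=[f"cell_{i:04d}" for i in range(n)],
        gene_ids=[f"gene_{j:04d}" for j in range(spec.d)],
    )
    if return_means:
        return X, coarse, fine, fine_means @ basis.T
    return X, coarse, fine


#: Fixed benchmark: 4 broad classes, one of which carries three subtypes
#: (9 fine clusters, 270 cells, 500 genes) — a deliberately solvable,
#: desk-scale analogue of a multi-tissue cell-line panel.
DEFAULT_BENCHMARK_SPEC = HierarchySpec(
    coarse_k=4,
    fine_per_coarse=(2, 2, 2, 3),
    n_per_fine=30,
    d=500,
    coarse_separation=10.0,
    fine_separation=6.0,
    coarse_dims=3,
    fine_dims=6,
    noise_sd=1.0,
    dropout_rate=0.0,
    seed=7,
)


def default_benchmark() -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """The fixed-seed benchmark instance (identical on every call)."""
    return generate(DEFAULT_BENCHMARK_SPEC)
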