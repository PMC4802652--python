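import numpy as np
import pytest

import pcareduce as pr


@pytest.fixture(scope="session")
def benchmark():
    """The fixed default benchmark: 270 cells, 500 genes, 4 coarse / 9 fine."""
    return pr.default_benchmark()


@pytest.fixture(scope="session")
def benchmark_runs(benchmark):
    """Twenty sampling-strategy hierarchies on the benchmark (shared across
    structure, parameter-recovery and consensus tests)."""
    X, _, _ = benchmark
    return pr.run_ensemble(X, k_init=12, n_runs=20, seed=11)


@pytest.fixture()
def two_blobs():
    """Two 5-D Gaussian blobs 20 within-cluster SDs apart, 30 cells each."""
    rng = np.random.default_rng(0)
    values = np.vstack(
        [rng.normal(0.0, 1.0, (30, 5)), rng.normal(20.0, 1.0, (30, 5))]
    )
    truth = np.repeat([1, 2], 30)
    return pr.ExpressionMatrix(values), truth


@pytest.fixture()
def tiny_sim():
    """A small, quick synthetic instance for IO / CLI round-trips."""
    spec = pr.HierarchySpec(
        coarse_k=2, fine_per_coarse=2, n_per_fine=8, d=30,
        coarse_separation=10.0, fine_separation=6.0,
        coarse_dims=1, fine_dims=2, seed=5,
    )
    return pr.generate(spec)
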