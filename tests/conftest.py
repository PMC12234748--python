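import numpy as np
import pytest

import clustervelo as cv


@pytest.fixture(scope="session")
def linear_fixture():
    """Moderate-noise linear fixture, shared read-only across tests."""
    return cv.make_fixture("linear", seed=0, n_cells=800, n_genes=60)


@pytest.fixture(scope="session")
def linear_run(linear_fixture):
    adata, truth = linear_fixture
    res = cv.run_pipeline(adata.copy(), cv.PipelineConfig(), mode="fit")
    return res, truth


@pytest.fixture(scope="session")
def noiseless_linear():
    return cv.make_fixture("linear", seed=1, n_cells=800, n_genes=60,
                           noise="none")


@pytest.fixture(scope="session")
def noiseless_run(noiseless_linear):
    adata, truth = noiseless_linear
    res = cv.run_pipeline(adata.copy(), cv.PipelineConfig(), mode="simple_fit")
    return res, truth


@pytest.fixture()
def toy_adata():
    """Tiny deterministic dataset with two well separated clusters."""
    rng = np.random.default_rng(0)
    n = 60
    half = n // 2
    s = np.vstack([rng.poisson(5.0, (half, 20)),
                   rng.poisson(5.0, (half, 20)) + 40.0])
    u = np.vstack([rng.poisson(2.0, (half, 20)),
                   rng.poisson(2.0, (half, 20)) + 20.0])
    cluster = ["a"] * half + ["b"] * half
    return cv.make_dataset(s.astype(float), u.astype(float), cluster=cluster)


def chain_graph(weights=None, sizes=None, nodes=("o", "a", "b")):
    """Small explicit cluster graph helper used across graph tests."""
    C = len(nodes)
    if weights is None:
        weights = np.zeros((C, C))
        for i in range(C - 1):
            weights[i, i + 1] = weights[i + 1, i] = 0.8
    if sizes is None:
        sizes = np.full(C, 10.0)
    return cv.ClusterGraph(nodes=list(nodes), sizes=np.asarray(sizes, float),
                           weights=np.asarray(weights, float))
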