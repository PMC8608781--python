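import numpy as np
import pytest

from wsbm import FitConfig, WSBMParams, builtin_setting, sample_wsbm


@pytest.fixture(scope="session")
def two_class() -> WSBMParams:
    return builtin_setting("two_class")


@pytest.fixture(scope="session")
def three_class() -> WSBMParams:
    return builtin_setting("three_class")


@pytest.fixture(scope="session")
def small_params() -> WSBMParams:
    """A hand-sized asymmetric two-block model for unit tests."""
    return WSBMParams(
        theta=[0.6, 0.4],
        pi=[[0.7, 0.3], [0.4, 0.6]],
        alpha=[[2.0, 1.0], [0.5, 3.0]],
        beta=[[1.0, 2.0], [0.3, 1.0]],
    )


@pytest.fixture(scope="session")
def small_graph(small_params):
    graph, z = sample_wsbm(small_params, 12, seed=7)
    return graph, z


@pytest.fixture(scope="session")
def quick_fit() -> FitConfig:
    return FitConfig(restarts=3, max_iter=100)


def random_params(rng: np.random.Generator, Q: int) -> WSBMParams:
    """Random well-conditioned parameter set for property tests."""
    theta = rng.dirichlet(np.full(Q, 5.0))
    return WSBMParams(
        theta=theta,
        pi=rng.uniform(0.2, 0.8, size=(Q, Q)),
        alpha=rng.uniform(0.3, 5.0, size=(Q, Q)),
        beta=rng.uniform(0.2, 3.0, size=(Q, Q)),
    )
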