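import numpy as np
import pytest

from ndd import (
    InteractionMatrix,
    SimilarityMatrix,
    SyntheticSpec,
    generate_benchmark,
)

#: compact benchmark reused by the slower integration tests (24 drugs keeps
#: a full CV run under a couple of seconds)
SMALL_SPEC = SyntheticSpec(m=24, n_clusters=4, seed=7)


@pytest.fixture(scope="session")
def small_benchmark():
    views, Y, truth = generate_benchmark(SMALL_SPEC)
    return views, Y, truth


@pytest.fixture
def toy_Y():
    # 2-drug universe with the single possible interaction present
    return InteractionMatrix(Y=np.array([[0, 1], [1, 0]]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_similarity(rng, m, name="v"):
    A = rng.random((m, m))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return SimilarityMatrix(name=name, A=A)
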