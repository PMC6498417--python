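import numpy as np
import pytest

from hnccorr.movie_io import Movie, Patch
from hnccorr.similarity import SimilarityGraph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_movie(rng):
    """Pure i.i.d.-noise movie, 12x12, T=400."""
    return Movie(data=rng.normal(0, 1, size=(400, 12, 12)))


def make_patch(data: np.ndarray) -> Patch:
    """Wrap a (T, m, m) array as a patch at origin (0, 0)."""
    return Patch(data=np.asarray(data, dtype=np.float64), origin=(0, 0), m=data.shape[1])


def random_seeded_instance(rng, n_max=12):
    """Random small seeded graph instance for solver/oracle tests.

    Returns an HncInstance on n in [4, n_max] nodes with ~half of all
    pairs as edges, U(0,1] weights and one random positive/negative seed
    pair.
    """
    from hnccorr.hnc import HncInstance

    n = int(rng.integers(4, n_max + 1))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.5]
    if not pairs:  # guarantee at least one edge
        pairs = [(0, 1)]
    edges = np.array(pairs, dtype=np.int64)
    weights = rng.uniform(1e-3, 1.0, size=len(pairs))
    graph = SimilarityGraph(num_nodes=n, edges=edges, weights=weights, alpha=1.0)
    perm = rng.permutation(n)
    return HncInstance(
        graph=graph,
        positive_seeds=frozenset({int(perm[0])}),
        negative_seeds=frozenset({int(perm[1])}),
    )
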