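"""Similarity-graph construction with the (sim)^2 measure.

Plain pairwise correlation declares two background pixels dissimilar —
they are both just noise.  (sim)^2 ("similarity of similarities")
instead represents each pixel by its *correlation image*: the vector
R_i of correlations between pixel i and a reference set of pixels.  Two
background pixels have nearly identical, near-zero correlation images,
so they come out highly similar; pixels of one cell share the cell's
signature in R and are likewise similar to each other.  Edge weights
are Gaussian similarities of the feature vectors,

    w_ij = exp(-alpha * ||R_i - R_j||^2),

so w_ij in (0, 1], with 1 for identical correlation images.

Computing all |V|^2 weights is wasteful; sparse computation projects
the feature vectors to p dimensions with (approximate) PCA, overlays a
grid with kappa sections per dimension, and keeps only pixel pairs in
the same or adjacent grid blocks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .movie_io import Patch
from .seeds import standardized_traces

__all__ = [
    "FeatureMatrix",
    "SimilarityGraph",
    "sample_reference_set",
    "compute_features",
    "sparse_edges",
    "weigh_edges",
    "graph_from_patch",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """(sim)^2 feature vectors of a patch.

    ``vectors[i, h] = corr(i, reference_set[h])`` with pixels flattened
    row-major; entries lie in [-1, 1] and zero-variance traces yield 0.
    """

    vectors: np.ndarray  # (|V|, |RS|)
    reference_set: np.ndarray  # (|RS|,) flat pixel ids

    @property
    def num_pixels(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class SimilarityGraph:
    """Sparse weighted similarity graph over patch pixels.

    ``edges`` holds unordered pixel-id pairs (i < j), no self-loops;
    ``weights[e] = exp(-alpha * ||R_i - R_j||^2) in (0, 1]``.
    """

    num_nodes: int
    edges: np.ndarray  # (E, 2) int
    weights: np.ndarray  # (E,) float
    alpha: float

    def degrees(self) -> np.ndarray:
        """Weighted degree d_i of every node (0 for isolated nodes)."""
        d = np.zeros(self.num_nodes)
        np.add.at(d, self.edges[:, 0], self.weights)
        np.add.at(d, self.edges[:, 1], self.weights)
        return d


def sample_reference_set(patch: Patch, gamma: float, rng_seed: int) -> np.ndarray:
    """Draw ceil(gamma * |V|) reference pixels i.i.d. with replacement.

    gamma >= 0.25 loses essentially nothing relative to the full patch;
    the default used throughout the package is 0.32.
    """
    if not (0 < gamma <= 1):
        raise ValueError("gamma must lie in (0, 1]")
    n = patch.num_pixels
    size = int(np.ceil(gamma * n))
    rng = np.random.default_rng(rng_seed)
    return rng.integers(0, n, size=size)


def compute_features(patch: Patch, reference_set: np.ndarray) -> FeatureMatrix:
    """Correlation image of every patch pixel against the reference set."""
    T = patch.data.shape[0]
    if T < 3:
        raise ValueError("need at least 3 frames to compute correlations")
    z = standardized_traces(patch.data.reshape(T, -1))  # (T, |V|)
    vectors = z.T @ z[:, reference_set]  # Pearson r via standardized dot products
    np.clip(vectors, -1.0, 1.0, out=vectors)
    return FeatureMatrix(vectors=vectors, reference_set=np.asarray(reference_set))


def _block_indices(features: FeatureMatrix, p: int, kappa: int, rng_seed: int) -> np.ndarray:
    """Project features to p dims (approximate PCA) and grid-quantize.

    Each projected dimension is min-max rescaled to [0, 1); points at the
    max land in the last block.  Returns (|V|, p) integer block indices.
    """
    X = features.vectors
    if np.ptp(X, axis=0).max() == 0:  # all feature vectors identical
        return np.zeros((X.shape[0], p), dtype=np.int64)
    n_comp = min(p, X.shape[1], max(X.shape[0] - 1, 1))
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=rng_seed)
    proj = pca.fit_transform(X)
    lo = proj.min(axis=0)
    span = proj.max(axis=0) - lo
    span[span == 0] = 1.0  # degenerate dimension: everything in block 0
    unit = (proj - lo) / span
    return np.minimum((unit * kappa).astype(np.int64), kappa - 1)


def sparse_edges(
    features: FeatureMatrix, p: int, kappa: int, rng_seed: int
) -> np.ndarray:
    """Select the relevant pixel pairs via grid blocks in PCA space.

    Two pixels form an edge iff their grid blocks coincide or are
    adjacent (Chebyshev distance <= 1 in block indices).  Returns an
    (E, 2) array of pairs with i < j and no self-pairs.
    """
    if p < 1 or kappa < 1:
        raise ValueError("p and kappa must be >= 1")
    blocks = _block_indices(features, p, kappa, rng_seed)
    ndim = blocks.shape[1]
    uniq, inverse = np.unique(blocks, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(len(uniq) + 1))
    occupied: dict[tuple[int, ...], np.ndarray] = {
        tuple(uniq[u]): order[bounds[u] : bounds[u + 1]] for u in range(len(uniq))
    }
    pairs: list[np.ndarray] = []
    for key, members in occupied.items():
        # within-block pairs
        if len(members) > 1:
            i, j = np.triu_indices(len(members), k=1)
            pairs.append(np.column_stack([members[i], members[j]]))
        # cross-block pairs; visit each unordered block pair once
        for offset in itertools.product((-1, 0, 1), repeat=ndim):
            if offset <= (0,) * ndim:
                continue
            other = tuple(k + o for k, o in zip(key, offset))
            if other in occupied:
                a, b = np.meshgrid(members, occupied[other], indexing="ij")
                pairs.append(np.column_stack([a.ravel(), b.ravel()]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.concatenate(pairs)
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def weigh_edges(
    features: FeatureMatrix, edges: np.ndarray, alpha: float = 1.0
) -> SimilarityGraph:
    """Attach Gaussian similarity weights to the selected edges."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    diff = features.vectors[edges[:, 0]] - features.vectors[edges[:, 1]]
    sqdist = (diff**2).sum(axis=1)
    weights = np.exp(-alpha * sqdist)
    return SimilarityGraph(
        num_nodes=features.num_pixels, edges=edges, weights=weights, alpha=alpha
    )


def graph_from_patch(
    patch: Patch,
    gamma: float = 0.32,
    alpha: float = 1.0,
    p: int = 3,
    kappa: int = 25,
    rng_seed: int = 0,
) -> tuple[SimilarityGraph, FeatureMatrix]:
    """Convenience: reference set -> features -> sparse edges -> weights."""
    rs = sample_reference_set(patch, gamma, rng_seed)
    features = compute_features(patch, rs)
    edges = sparse_edges(features, p, kappa, rng_seed)
    graph = weigh_edges(features, edges, alpha)
    return graph, features
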