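"""(sim)^2 features, sparse-computation edge selection, Gaussian weights."""

import itertools

import numpy as np
import pytest

from hnccorr.similarity import (
    FeatureMatrix,
    compute_features,
    sample_reference_set,
    sparse_edges,
    weigh_edges,
)
from hnccorr.synth import SynthConfig, generate, signal_variance

from conftest import make_patch


class TestSampleReferenceSet:
    def test_count_is_ceil_gamma_v(self, rng):
        patch = make_patch(rng.normal(size=(5, 31, 31)))
        assert len(sample_reference_set(patch, 1.0, 0)) == 961
        assert len(sample_reference_set(patch, 0.32, 0)) == 308  # ceil(.32*961)

    def test_reproducible_from_seed(self, rng):
        patch = make_patch(rng.normal(size=(5, 9, 9)))
        a = sample_reference_set(patch, 0.5, 42)
        b = sample_reference_set(patch, 0.5, 42)
        np.testing.assert_array_equal(a, b)

    def test_draws_are_with_replacement(self, rng):
        patch = make_patch(rng.normal(size=(5, 31, 31)))
        rs = sample_reference_set(patch, 1.0, 3)
        assert len(np.unique(rs)) < len(rs)  # collisions certain at |V| draws


class TestComputeFeatures:
    def test_self_correlation_is_one(self, rng):
        patch = make_patch(rng.normal(size=(50, 5, 5)))
        rs = np.arange(25)
        F = compute_features(patch, rs)
        np.testing.assert_allclose(np.diag(F.vectors), 1.0, atol=1e-12)

    def test_identical_traces_identical_rows(self, rng):
        data = rng.normal(size=(30, 3, 3))
        data[:, 2, 2] = data[:, 0, 0]
        F = compute_features(make_patch(data), np.arange(9))
        np.testing.assert_allclose(F.vectors[8], F.vectors[0], atol=1e-12)

    def test_negated_trace_flips_sign(self, rng):
        data = rng.normal(size=(30, 3, 3))
        data[:, 2, 2] = -data[:, 0, 0]
        F = compute_features(make_patch(data), np.arange(9))
        np.testing.assert_allclose(F.vectors[8], -F.vectors[0], atol=1e-12)

    def test_zero_variance_trace_gives_zeros(self, rng):
        data = rng.normal(size=(30, 3, 3))
        data[:, 1, 1] = 5.0
        F = compute_features(make_patch(data), np.arange(9))
        np.testing.assert_array_equal(F.vectors[4], 0.0)

    def test_entries_bounded(self, rng):
        patch = make_patch(rng.normal(size=(10, 5, 5)))
        F = compute_features(patch, sample_reference_set(patch, 0.5, 0))
        assert np.all(F.vectors >= -1) and np.all(F.vectors <= 1)


def _brute_force_block_edges(blocks):
    """Oracle: all pairs whose blocks are within Chebyshev distance 1."""
    n = len(blocks)
    out = set()
    for i, j in itertools.combinations(range(n), 2):
        if np.max(np.abs(blocks[i] - blocks[j])) <= 1:
            out.add((i, j))
    return out


class TestSparseEdges:
    def test_identical_features_complete_graph(self):
        F = FeatureMatrix(vectors=np.ones((10, 5)), reference_set=np.arange(5))
        edges = sparse_edges(F, p=3, kappa=25, rng_seed=0)
        assert len(edges) == 45  # C(10, 2)

    def test_kappa_one_complete_graph(self, rng):
        F = FeatureMatrix(vectors=rng.normal(size=(12, 6)), reference_set=np.arange(6))
        edges = sparse_edges(F, p=2, kappa=1, rng_seed=0)
        assert len(edges) == 66

    def test_no_self_pairs_and_canonical_order(self, rng):
        F = FeatureMatrix(vectors=rng.normal(size=(30, 8)), reference_set=np.arange(8))
        edges = sparse_edges(F, p=3, kappa=5, rng_seed=0)
        assert np.all(edges[:, 0] < edges[:, 1])

    def test_separated_clusters_not_connected(self, rng):
        # two tight, far-apart clusters in feature space
        a = rng.normal(0, 0.01, size=(15, 10))
        b = rng.normal(0, 0.01, size=(15, 10)) + 5.0
        F = FeatureMatrix(vectors=np.vstack([a, b]), reference_set=np.arange(10))
        edges = sparse_edges(F, p=3, kappa=25, rng_seed=0)
        crossing = [(i, j) for i, j in edges if i < 15 <= j]
        assert not crossing

    def test_matches_block_arithmetic_oracle(self, rng):
        from hnccorr.similarity import _block_indices

        F = FeatureMatrix(vectors=rng.normal(size=(40, 12)), reference_set=np.arange(12))
        for kappa in (2, 4, 8):
            edges = sparse_edges(F, p=3, kappa=kappa, rng_seed=5)
            blocks = _block_indices(F, 3, kappa, 5)
            expected = _brute_force_block_edges(blocks)
            assert {tuple(e) for e in edges} == expected

    def test_edges_subset_of_complete_graph(self, rng):
        F = FeatureMatrix(vectors=rng.normal(size=(20, 5)), reference_set=np.arange(5))
        edges = sparse_edges(F, p=2, kappa=10, rng_seed=0)
        assert len(edges) <= 190


class TestWeighEdges:
    def test_identical_vectors_weight_one(self):
        F = FeatureMatrix(vectors=np.ones((2, 4)), reference_set=np.arange(4))
        g = weigh_edges(F, np.array([[0, 1]]), alpha=1.0)
        np.testing.assert_allclose(g.weights, 1.0)

    def test_unit_distance_closed_form(self):
        v = np.zeros((2, 4))
        v[1, 0] = 1.0  # squared distance exactly 1
        F = FeatureMatrix(vectors=v, reference_set=np.arange(4))
        g = weigh_edges(F, np.array([[0, 1]]), alpha=1.0)
        np.testing.assert_allclose(g.weights[0], np.exp(-1.0))

    def test_alpha_zero_all_ones(self, rng):
        F = FeatureMatrix(vectors=rng.normal(size=(6, 3)), reference_set=np.arange(3))
        edges = np.array([[0, 1], [2, 5], [3, 4]])
        g = weigh_edges(F, edges, alpha=0.0)
        np.testing.assert_allclose(g.weights, 1.0)

    def test_monotone_in_feature_distance(self, rng):
        base = rng.normal(size=4)
        v = np.vstack([base, base + 0.1, base + 0.5])
        F = FeatureMatrix(vectors=v, reference_set=np.arange(4))
        g = weigh_edges(F, np.array([[0, 1], [0, 2]]), alpha=1.0)
        assert g.weights[0] > g.weights[1]

    def test_weights_in_unit_interval(self, rng):
        F = FeatureMatrix(vectors=rng.normal(size=(10, 6)), reference_set=np.arange(6))
        edges = np.array(list(itertools.combinations(range(10), 2)))
        g = weigh_edges(F, edges, alpha=1.0)
        assert np.all(g.weights > 0) and np.all(g.weights <= 1)

    def test_degrees_consistent_with_edges(self):
        F = FeatureMatrix(vectors=np.zeros((3, 2)), reference_set=np.arange(2))
        g = weigh_edges(F, np.array([[0, 1], [1, 2]]), alpha=1.0)
        np.testing.assert_allclose(g.degrees(), [1.0, 2.0, 1.0])


def _background_cell_weight_gap(seed: int) -> float:
    """Mean background-background minus background-cell edge weight.

    One correlated cell in an i.i.d.-noise patch at matched signal and
    noise variance; weights from the full (sim)^2 route.
    """
    cfg = SynthConfig(
        frame_shape=(31, 31),
        T=1000,
        n_cells=1,
        radius_range=(5.0, 5.0),
        min_center_spacing=1.0,
        background=0.0,
        rng_seed=seed,
    )
    assert abs(cfg.resolved_noise_sd() ** 2 - signal_variance(cfg)) < 1e-12
    movie, truth, _ = generate(cfg)
    patch = make_patch(movie.data)
    rs = sample_reference_set(patch, 0.32, seed)
    F = compute_features(patch, rs)
    cell_ids = {r * 31 + c for r, c in truth[0].pixels}
    bg_ids = sorted(set(range(961)) - cell_ids)
    cell_ids = sorted(cell_ids)
    rng = np.random.default_rng(seed)
    bg_pairs = np.array(
        [(a, b) for a, b in zip(rng.choice(bg_ids, 400), rng.choice(bg_ids, 400)) if a != b]
    )
    mixed_pairs = np.column_stack(
        [rng.choice(bg_ids, 400), rng.choice(cell_ids, 400)]
    )
    w_bg = weigh_edges(F, bg_pairs, 1.0).weights.mean()
    w_mixed = weigh_edges(F, mixed_pairs, 1.0).weights.mean()
    return float(w_bg - w_mixed)


def test_background_pixels_more_similar_to_each_other_than_to_cell():
    """The core (sim)^2 mechanism: mutually uncorrelated background pixels
    have nearly identical correlation images, so background-background
    weights exceed background-cell weights on average."""
    gaps = [_background_cell_weight_gap(seed) for seed in range(3)]
    assert all(g > 0 for g in gaps)
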