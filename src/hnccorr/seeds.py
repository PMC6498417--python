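"""Seed selection.

Positive seeds mark candidate cell locations.  A pixel is a good
candidate when its fluorescence trace correlates strongly with its
immediate neighbours — pixels of one cell share the cell's temporal
signal.  The selector scores every pixel by its mean Pearson correlation
with its 8-neighbourhood, keeps the best pixel per grid block, and
processes the top fraction of blocks.  For each chosen center, the
positive seed is a k x k superpixel and the negative seeds sit on a
circle of radius rho around it, constraining the cluster to stay inside
the circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .movie_io import Movie, Patch

__all__ = [
    "SeedCandidateList",
    "SeedSet",
    "neighbor_correlation_map",
    "select_positive_seeds",
    "build_seed_set",
]


@dataclass(frozen=True)
class SeedCandidateList:
    """Candidate seed centers, ordered by score (descending)."""

    centers: tuple[tuple[int, int], ...]
    scores: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class SeedSet:
    """Positive superpixel plus ring of negative seeds, in patch coordinates."""

    positive: frozenset[tuple[int, int]]
    negative: tuple[tuple[int, int], ...]
    center: tuple[int, int]

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative seeds overlap")


def standardized_traces(data: np.ndarray) -> np.ndarray:
    """Standardize per-pixel traces so that dot products give Pearson r.

    Input ``(T, H, W)`` (or ``(T, N)``); output has zero mean and is
    scaled by ``sqrt(T-1) * sample_sd``, hence ``corr(u, v) = z_u . z_v``.
    Zero-variance traces map to the zero vector, realizing the shared
    convention that their correlation with anything (themselves included)
    is 0.
    """
    x = np.asarray(data, dtype=np.float64)
    centered = x - x.mean(axis=0)
    # ||centered|| = sqrt(T-1) * sample sd
    norm = np.sqrt((centered**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norm
    z[:, norm == 0] = 0.0
    return z


_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def neighbor_correlation_map(movie: Movie) -> np.ndarray:
    """Mean correlation of each pixel with its existing 8-neighbours.

    Border pixels average over their 3 or 5 in-frame neighbours.
    Requires T >= 3 so the sample correlation is meaningful.
    """
    if movie.num_frames < 3:
        raise ValueError("need at least 3 frames for neighbor correlations")
    z = standardized_traces(movie.data)  # (T, H, W)
    H, W = movie.frame_shape
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for dr, dc in _NEIGHBOR_OFFSETS:
        r0, r1 = max(dr, 0), H + min(dr, 0)
        s0, s1 = max(-dr, 0), H + min(-dr, 0)
        c0, c1 = max(dc, 0), W + min(dc, 0)
        d0, d1 = max(-dc, 0), W + min(-dc, 0)
        corr = (z[:, r0:r1, c0:c1] * z[:, s0:s1, d0:d1]).sum(axis=0)
        acc[r0:r1, c0:c1] += corr
        cnt[r0:r1, c0:c1] += 1
    return acc / cnt


def select_positive_seeds(
    scores: np.ndarray, n_grid: int, p_seed: float
) -> SeedCandidateList:
    """Pick one argmax pixel per ``n_grid x n_grid``-pixel block, keep the top fraction.

    With ``n_grid=1, p_seed=1.0`` this degenerates to full enumeration of
    all pixels.  Ties (within a block and in the final sort) are broken by
    smallest (row, col) for determinism.
    """
    if n_grid < 1:
        raise ValueError("n_grid must be >= 1")
    if not (0 < p_seed <= 1):
        raise ValueError("p_seed must lie in (0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    H, W = scores.shape
    centers: list[tuple[int, int]] = []
    for top in range(0, H, n_grid):
        for left in range(0, W, n_grid):
            block = scores[top : top + n_grid, left : left + n_grid]
            flat = int(np.argmax(block))  # first (smallest row, col) max
            r, c = divmod(flat, block.shape[1])
            centers.append((top + r, left + c))
    vals = np.array([scores[rc] for rc in centers])
    order = sorted(range(len(centers)), key=lambda i: (-vals[i], centers[i]))
    keep = math.ceil(p_seed * len(centers))
    kept = order[:keep]
    return SeedCandidateList(
        centers=tuple(centers[i] for i in kept),
        scores=tuple(float(vals[i]) for i in kept),
    )


def build_seed_set(
    center: tuple[int, int],
    patch: Patch,
    k: int,
    neg_radius: float,
    n_neg: int = 10,
    clip_to_patch: bool = False,
) -> SeedSet:
    """Build the positive superpixel and the negative-seed circle.

    ``center`` is in patch coordinates.  The positive seed is the k x k
    square around it, clipped to the patch.  The ``n_neg`` negative seeds
    sit at angles ``2*pi*h/n_neg`` (h = 0..n_neg-1, angle 0 pointing along
    +col, counterclockwise) on the circle of radius ``neg_radius``,
    rounded to the nearest pixel and deduplicated.

    For a patch shifted inward at the frame border the seed is
    off-center and part of the circle can leave the patch.  By default
    that is an error; with ``clip_to_patch=True`` the out-of-patch
    circle points are dropped instead (the frame edge already bounds the
    cluster on that side), keeping at least 4 negatives.
    """
    if k % 2 == 0:
        raise ValueError("superpixel size k must be odd")
    if n_neg < 4:
        raise ValueError("need at least 4 negative seeds")
    if neg_radius >= patch.m / 2:
        raise ValueError(
            f"negative-seed radius {neg_radius} must be < half the patch size {patch.m}"
        )
    m = patch.m
    r0, c0 = center
    if not (0 <= r0 < m and 0 <= c0 < m):
        raise ValueError(f"center {center} outside patch")
    half = k // 2
    positive = frozenset(
        (r, c)
        for r in range(max(r0 - half, 0), min(r0 + half + 1, m))
        for c in range(max(c0 - half, 0), min(c0 + half + 1, m))
    )
    negative: list[tuple[int, int]] = []
    for h in range(n_neg):
        theta = 2 * math.pi * h / n_neg
        # image rows grow downward, so counterclockwise means row - sin
        r = int(round(r0 - neg_radius * math.sin(theta)))
        c = int(round(c0 + neg_radius * math.cos(theta)))
        if not (0 <= r < m and 0 <= c < m):
            if clip_to_patch:
                continue
            raise ValueError(
                "negative-seed circle exits the patch; decrease the radius "
                "or recenter the patch"
            )
        if (r, c) not in negative:
            negative.append((r, c))
    if len(negative) < 4:
        raise ValueError("fewer than 4 negative seeds fall inside the patch")
    overlap = positive & set(negative)
    if overlap:
        raise ValueError(
            f"negative seeds {sorted(overlap)} fall inside the positive superpixel"
        )
    return SeedSet(positive=positive, negative=tuple(negative), center=(r0, c0))
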