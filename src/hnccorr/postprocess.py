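"""Size-based postprocessing and the movie-level detection loop.

The clustering step returns a nested chain of candidate clusters per
seed.  The postprocessor discards candidates whose pixel count falls
outside ``[n_min, n_max]``; if none survive the seed yields "no cell",
otherwise the survivor whose sqrt-size is closest to ``sqrt(n_avg)`` is
the cell's footprint (square root because cell area scales like a
circle's).  The pipeline runs this per candidate seed, skipping seeds
inside already-accepted footprints and discarding near-duplicate
footprints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import HNCcorrConfig
from .hnc import HncInstance, NestedClusters, solve_all_lambda
from .movie_io import Footprint, Movie, downsample_temporal, extract_patch
from .seeds import build_seed_set, neighbor_correlation_map, select_positive_seeds
from .similarity import graph_from_patch

__all__ = ["SizePolicy", "select_footprint", "run_pipeline"]

logger = logging.getLogger("hnccorr")


@dataclass(frozen=True)
class SizePolicy:
    """Acceptable and preferred cell sizes, in pixels."""

    n_min: int
    n_max: int
    n_avg: int

    def __post_init__(self) -> None:
        if not (0 < self.n_min <= self.n_avg <= self.n_max):
            raise ValueError("need 0 < n_min <= n_avg <= n_max")


def select_footprint(
    candidates: NestedClusters | list[frozenset[int]], policy: SizePolicy
) -> frozenset[int] | None:
    """Pick one cluster as the cell footprint, or None for "no cell".

    Among clusters with size in [n_min, n_max], returns the argmin of
    ``|sqrt(|S|) - sqrt(n_avg)|``; exact ties go to the smaller cluster.
    """
    clusters = candidates.clusters if isinstance(candidates, NestedClusters) else candidates
    feasible = [S for S in clusters if policy.n_min <= len(S) <= policy.n_max]
    if not feasible:
        return None
    target = math.sqrt(policy.n_avg)
    return min(feasible, key=lambda S: (abs(math.sqrt(len(S)) - target), len(S)))


def _patch_rng_seed(master_seed: int, center: tuple[int, int]) -> int:
    """Independent, reproducible rng stream per (movie, seed-center) pair."""
    ss = np.random.SeedSequence([master_seed, center[0], center[1]])
    return int(ss.generate_state(1)[0] % (2**31))


def _overlap_fraction(a: frozenset, b: frozenset) -> float:
    return len(a & b) / min(len(a), len(b))


def run_pipeline(movie: Movie, config: HNCcorrConfig) -> list[Footprint]:
    """Detect all cell footprints in a movie.

    Steps: temporal downsampling; neighbor-correlation seed scoring; then
    per candidate seed (best first): skip seeds inside accepted
    footprints, build the patch/seeds/similarity graph, solve the seeded
    clustering for all lambda, size-select a footprint.  A new footprint
    is dropped as a duplicate when it shares more than ``overlap_max``
    of the smaller footprint's pixels with any single accepted
    footprint, or more than ``overlap_max`` of its own pixels with the
    union of all accepted footprints (fragmented re-detections can
    straddle several cells without exceeding any pairwise overlap).
    Per-seed failures are logged and skipped, never fatal.
    """
    cfg = config
    movie_ds = downsample_temporal(movie, cfg.temporal_downsample)
    scores = neighbor_correlation_map(movie_ds)
    candidates = select_positive_seeds(scores, cfg.n_grid, cfg.p_seed)
    logger.info("processing %d candidate seeds", len(candidates))
    policy = SizePolicy(cfg.n_min, cfg.n_max, cfg.n_avg)
    accepted: list[Footprint] = []
    claimed: set[tuple[int, int]] = set()
    for center in candidates.centers:
        if center in claimed:
            logger.debug("seed %s: skipped (inside accepted footprint)", center)
            continue
        try:
            patch = extract_patch(movie_ds, center, cfg.patch_size)
            patch_center = patch.to_patch_coords(center)
            seed_set = build_seed_set(
                patch_center,
                patch,
                cfg.superpixel_size,
                cfg.neg_radius,
                cfg.n_neg,
                clip_to_patch=True,
            )
            rng_seed = _patch_rng_seed(cfg.master_seed, center)
            graph, _ = graph_from_patch(
                patch,
                gamma=cfg.gamma,
                alpha=cfg.alpha,
                p=cfg.sparse_p,
                kappa=cfg.kappa,
                rng_seed=rng_seed,
            )
            m = patch.m
            to_id = lambda rc: rc[0] * m + rc[1]
            instance = HncInstance(
                graph=graph,
                positive_seeds=frozenset(to_id(rc) for rc in seed_set.positive),
                negative_seeds=frozenset(to_id(rc) for rc in seed_set.negative),
            )
            nested = solve_all_lambda(instance)
            chosen = select_footprint(nested, policy)
        except Exception as exc:
            logger.warning("seed %s: skipped (%s)", center, exc)
            continue
        if chosen is None:
            logger.debug("seed %s: no cell", center)
            continue
        pixels = frozenset(
            patch.to_movie_coords(divmod(int(v), m)) for v in chosen
        )
        footprint = Footprint(pixels=pixels)
        pairwise_dup = any(
            _overlap_fraction(footprint.pixels, fp.pixels) > cfg.overlap_max
            for fp in accepted
        )
        claimed_frac = len(footprint.pixels & claimed) / len(footprint)
        if pairwise_dup or claimed_frac > cfg.overlap_max:
            logger.debug("seed %s: skipped (duplicate footprint)", center)
            continue
        accepted.append(footprint)
        claimed |= footprint.pixels
        logger.info("seed %s: accepted footprint of %d pixels", center, len(footprint))
    logger.info("detected %d cells", len(accepted))
    return accepted
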