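"""Detection scoring and activity classification.

Detections are scored against a reference annotation with the
Neurofinder matching rule: a reference cell and a detected cell match
when their centers of mass lie within 5 pixels (inclusive), each cell
matched at most once.  Matched pairs are true positives; unmatched
reference cells are false negatives and unmatched detections false
positives; precision, recall and F1 follow.

The activity classifier is a deliberately approximate heuristic: a
cell counts as active when the dF/F of its mean-intensity trace (with
the trace median as the f0 baseline) exceeds median + 3.5 sample SDs
at three or more, not necessarily consecutive, time steps of the
10-frame-averaged movie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movie_io import Footprint, Movie

__all__ = ["MatchResult", "center_of_mass", "match", "classify_activity"]


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...]  # (reference index, detected index)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def center_of_mass(footprint: Footprint) -> tuple[float, float]:
    """Unweighted mean (row, col) of the footprint's pixels."""
    pts = np.array(sorted(footprint.pixels), dtype=np.float64)
    r, c = pts.mean(axis=0)
    return float(r), float(c)


def match(
    reference: list[Footprint],
    detected: list[Footprint],
    threshold: float = 5.0,
) -> MatchResult:
    """Greedy center-of-mass matching, closest pairs first.

    Candidate pairs with distance <= threshold are processed in
    ascending distance order (ties by reference then detected index);
    each cell participates in at most one match.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ref_com = [center_of_mass(fp) for fp in reference]
    det_com = [center_of_mass(fp) for fp in detected]
    candidates = []
    for i, (ri, ci) in enumerate(ref_com):
        for j, (rj, cj) in enumerate(det_com):
            d = float(np.hypot(ri - rj, ci - cj))
            if d <= threshold:
                candidates.append((d, i, j))
    candidates.sort()
    used_ref: set[int] = set()
    used_det: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_ref or j in used_det:
            continue
        pairs.append((i, j))
        used_ref.add(i)
        used_det.add(j)
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(detected) - tp, fn=len(reference) - tp, pairs=tuple(pairs)
    )


def classify_activity(
    movie: Movie,
    footprint: Footprint,
    sd_factor: float = 3.5,
    min_timesteps: int = 3,
) -> str:
    """Classify an annotated cell as "active" or "inactive".

    ``movie`` is expected to be the 10-frame-averaged movie.  The cell
    trace is the per-frame mean intensity over the footprint; dF/F uses
    the trace median as baseline f0.  This heuristic is approximate by
    construction — its output should only be read as a coarse
    active/inactive split, not as spike inference.
    """
    rows, cols = zip(*sorted(footprint.pixels))
    trace = movie.data[:, rows, cols].mean(axis=1)
    f0 = np.median(trace)
    if f0 == 0:
        f0 = 1.0  # arbitrary positive baseline; only thresholds matter
    dff = (trace - np.median(trace)) / f0
    sd = dff.std(ddof=1)
    if sd == 0:
        return "inactive"
    n_exceed = int((dff > np.median(dff) + sd_factor * sd).sum())
    return "active" if n_exceed >= min_timesteps else "inactive"
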