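"""Seeded HNC clustering, solved for all trade-off values simultaneously.

For a weighted similarity graph with positive seeds (forced into the
cluster S) and negative seeds (forced out), lambda-HNC minimizes

    cut(S, S-bar) - lambda * (total weight of edges inside S),

trading distinctness of S against its coherence.  Using
``sum_{i,j in S} w_ij = (sum_{i in S} d_i - cut(S, S-bar)) / 2`` with
weighted degrees d_i, the objective is, up to a positive factor and an
additive constant, ``cut(S, S-bar) - mu * sum_{i in S} d_i`` with
``mu = lambda / (lambda + 2) in [0, 1)``.  That is a monotone parametric
s-t min-cut: a source s with arcs ``s -> i`` of capacity ``mu * d_i``,
infinite arcs pinning the seeds, and each graph edge as an opposite arc
pair of capacity w_ij.  Source-side capacities grow with mu, so the
optimal clusters are nested and there are at most |V| distinct ones; the
solver finds every breakpoint by recursive bisection on mu, one min cut
per probe.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._maxflow import FlowNetwork
from .similarity import SimilarityGraph

__all__ = [
    "HncInstance",
    "NestedClusters",
    "hnc_objective",
    "solve_all_lambda",
    "brute_force_hnc",
]

_TOL = 1e-11


@dataclass(frozen=True)
class HncInstance:
    """A seeded clustering instance on a similarity graph."""

    graph: SimilarityGraph
    positive_seeds: frozenset[int]
    negative_seeds: frozenset[int]

    def __post_init__(self) -> None:
        if not self.positive_seeds or not self.negative_seeds:
            raise ValueError("both seed sets must be nonempty")
        if self.positive_seeds & self.negative_seeds:
            raise ValueError("seed sets must be disjoint")
        n = self.graph.num_nodes
        for v in self.positive_seeds | self.negative_seeds:
            if not (0 <= v < n):
                raise ValueError(f"seed {v} outside node range")

    @property
    def degrees(self) -> np.ndarray:
        return self.graph.degrees()


@dataclass(frozen=True)
class NestedClusters:
    """The solver's output: the nested chain of optimal clusters.

    ``clusters[i]`` is optimal exactly for lambda in the i-th interval;
    ``boundaries`` holds the lambda breakpoints between consecutive
    clusters, so cluster i covers [boundaries[i-1], boundaries[i]) with
    boundaries[-1] = 0 and boundaries[l-1] = +inf implied.  At an exact
    breakpoint both neighbours are optimal; ``cluster_at`` resolves the
    tie to the smaller cluster, matching the minimal-min-cut convention.
    """

    clusters: tuple[frozenset[int], ...]
    boundaries: tuple[float, ...]  # len(clusters) - 1 breakpoints, increasing

    def __post_init__(self) -> None:
        assert len(self.boundaries) == len(self.clusters) - 1

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_at(self, lam: float) -> frozenset[int]:
        """The optimal cluster at a given lambda (ties -> smaller cluster)."""
        return self.clusters[bisect.bisect_left(self.boundaries, lam)]

    def intervals(self) -> list[tuple[float, float]]:
        """Lambda interval per cluster; together they cover [0, inf)."""
        pts = (0.0, *self.boundaries, np.inf)
        return list(zip(pts[:-1], pts[1:]))

    def describe(self) -> str:
        """Tabular text dump of (lambda interval, cluster size) pairs."""
        lines = ["lambda_lo\tlambda_hi\tcluster_size"]
        for cluster, (lo, hi) in zip(self.clusters, self.intervals()):
            lines.append(f"{lo:.6g}\t{hi:.6g}\t{len(cluster)}")
        return "\n".join(lines)


def hnc_objective(instance: HncInstance, S: frozenset[int] | set[int], lam: float) -> float:
    """Distinctness minus lambda times coherence for a feasible cluster S."""
    S = frozenset(S)
    if not instance.positive_seeds <= S:
        raise ValueError("cluster must contain every positive seed")
    if S & instance.negative_seeds:
        raise ValueError("cluster must exclude every negative seed")
    g = instance.graph
    in_s = np.zeros(g.num_nodes, dtype=bool)
    in_s[list(S)] = True
    a, b = in_s[g.edges[:, 0]], in_s[g.edges[:, 1]]
    cut = g.weights[a ^ b].sum()
    within = g.weights[a & b].sum()
    return float(cut - lam * within)


class _ParametricSolver:
    """Min cut of ``cut(S) - mu * sum_{i in S} d_i`` as a function of mu."""

    def __init__(self, instance: HncInstance):
        g = instance.graph
        n = g.num_nodes
        self.n = n
        self.s, self.t = n, n + 1
        self.deg = instance.degrees
        pos = sorted(instance.positive_seeds)
        neg = sorted(instance.negative_seeds)
        free = [i for i in range(n) if i not in instance.positive_seeds]
        self.free = np.array(free, dtype=np.int64)
        # Arcs in forward/reverse pairs.
        frm: list[int] = []
        to: list[int] = []
        caps: list[float] = []
        for (i, j), w in zip(g.edges, g.weights):
            frm += [int(i), int(j)]
            to += [int(j), int(i)]
            caps += [float(w), float(w)]
        inf_cap = 2.0 * g.weights.sum() + self.deg.sum() + 1.0
        for i in pos:
            frm += [self.s, i]
            to += [i, self.s]
            caps += [inf_cap, 0.0]
        for i in neg:
            frm += [i, self.t]
            to += [self.t, i]
            caps += [inf_cap, 0.0]
        self.source_arc = np.full(n, -1, dtype=np.int64)
        for i in free:
            self.source_arc[i] = len(frm)
            frm += [self.s, i]
            to += [i, self.s]
            caps += [0.0, 0.0]
        self.base_caps = np.array(caps)
        self.network = FlowNetwork(
            n + 2, np.array(frm, dtype=np.int64), np.array(to, dtype=np.int64)
        )
        self._cache: dict[float, frozenset[int]] = {}

    def solve(self, mu: float) -> frozenset[int]:
        """Minimal optimal cluster at a fixed mu."""
        if mu in self._cache:
            return self._cache[mu]
        caps = self.base_caps.copy()
        caps[self.source_arc[self.free]] = mu * self.deg[self.free]
        _, side = self.network.min_cut(caps, self.s, self.t)
        cluster = frozenset(int(v) for v in np.nonzero(side[: self.n])[0])
        self._cache[mu] = cluster
        return cluster


def _cut_and_degsum(instance: HncInstance, S: frozenset[int]) -> tuple[float, float]:
    g = instance.graph
    in_s = np.zeros(g.num_nodes, dtype=bool)
    in_s[list(S)] = True
    a, b = in_s[g.edges[:, 0]], in_s[g.edges[:, 1]]
    cut = float(g.weights[a ^ b].sum())
    degsum = float(instance.degrees[list(S)].sum())
    return cut, degsum


def _mu_to_lambda(mu: float) -> float:
    return 2.0 * mu / (1.0 - mu)


_MU_MAX = 1.0 - 1e-9


def solve_all_lambda(instance: HncInstance) -> NestedClusters:
    """Globally optimal clusters for every lambda >= 0 at once.

    Recursive bisection on mu: solve at the interval endpoints; when the
    optima differ, probe at the mu where their objective lines cross.
    If the probe reveals no new cluster the crossing is a breakpoint;
    otherwise recurse on both halves.  Terminates after O(l) min cuts
    for l <= |V| distinct clusters.
    """
    solver = _ParametricSolver(instance)
    lines: dict[frozenset[int], tuple[float, float]] = {}

    def line(S: frozenset[int]) -> tuple[float, float]:
        if S not in lines:
            lines[S] = _cut_and_degsum(instance, S)
        return lines[S]

    pieces: list[tuple[float, frozenset[int]]] = []  # (mu where piece starts, S)

    def recurse(mu_lo: float, S_lo: frozenset[int], mu_hi: float, S_hi: frozenset[int]) -> None:
        if S_lo == S_hi:
            return
        c_lo, d_lo = line(S_lo)
        c_hi, d_hi = line(S_hi)
        if d_hi - d_lo <= _TOL:
            # parallel lines: same objective everywhere they are optimal;
            # keep the smaller cluster throughout (minimal convention)
            return
        mu_x = (c_hi - c_lo) / (d_hi - d_lo)
        mu_x = min(max(mu_x, mu_lo), mu_hi)
        S_mid = solver.solve(mu_x)
        f_mid = line(S_mid)[0] - mu_x * line(S_mid)[1]
        f_lo = c_lo - mu_x * d_lo
        if S_mid not in (S_lo, S_hi) and f_mid < f_lo - _TOL:
            recurse(mu_lo, S_lo, mu_x, S_mid)
            recurse(mu_x, S_mid, mu_hi, S_hi)
        else:
            pieces.append((mu_x, S_hi))

    S_first = solver.solve(0.0)
    S_last = solver.solve(_MU_MAX)
    pieces.append((0.0, S_first))
    recurse(0.0, S_first, _MU_MAX, S_last)
    pieces.sort(key=lambda x: (x[0], len(x[1])))
    clusters: list[frozenset[int]] = []
    bounds: list[float] = []
    for mu, S in pieces:
        if clusters and S == clusters[-1]:
            continue
        if clusters:
            bounds.append(_mu_to_lambda(mu))
        clusters.append(S)
    return NestedClusters(clusters=tuple(clusters), boundaries=tuple(bounds))


def brute_force_hnc(instance: HncInstance, lam: float) -> frozenset[int]:
    """Exhaustive lambda-HNC oracle for tiny instances (|V| <= ~15).

    Enumerates every feasible cluster and returns the minimizer; among
    ties (within 1e-11) the minimal cluster, matching the solver's
    minimal-min-cut convention.
    """
    n = instance.graph.num_nodes
    if n > 15:
        raise ValueError("brute force limited to at most 15 nodes")
    free = sorted(set(range(n)) - instance.positive_seeds - instance.negative_seeds)
    base = frozenset(instance.positive_seeds)
    best: list[frozenset[int]] = []
    best_val = np.inf
    for r in range(len(free) + 1):
        for extra in combinations(free, r):
            S = base | frozenset(extra)
            val = hnc_objective(instance, S, lam)
            if val < best_val - _TOL:
                best, best_val = [S], val
            elif val <= best_val + _TOL:
                best.append(S)
                best_val = min(best_val, val)
    minimal = frozenset.intersection(*best)
    if any(S == minimal for S in best):
        return minimal
    return min(best, key=lambda S: (len(S), tuple(sorted(S))))
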