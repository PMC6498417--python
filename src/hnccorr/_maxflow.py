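"""Dinic max-flow with float capacities, JIT-compiled with numba.

The parametric solver needs many s-t min cuts per patch on graphs with
real-valued capacities, and it needs the *minimal* source side (the set
of nodes reachable from s in the final residual graph), which is the
unique smallest minimizer of the cut.  Arcs are stored in pairs: arc
``a`` and its reverse ``a ^ 1`` share storage, so pushing flow on one
adds residual capacity to the other.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _max_flow(num_nodes, s, t, arc_to, res, adj_ptr, adj_idx):  # pragma: no cover
    """Run Dinic on the residual array ``res`` (modified in place)."""
    level = np.empty(num_nodes, np.int64)
    iters = np.empty(num_nodes, np.int64)
    queue = np.empty(num_nodes, np.int64)
    path = np.empty(num_nodes, np.int64)
    total = 0.0
    while True:
        # BFS phase: level graph
        for i in range(num_nodes):
            level[i] = -1
        level[s] = 0
        qh, qt = 0, 1
        queue[0] = s
        while qh < qt:
            u = queue[qh]
            qh += 1
            for k in range(adj_ptr[u], adj_ptr[u + 1]):
                a = adj_idx[k]
                v = arc_to[a]
                if res[a] > _EPS and level[v] < 0:
                    level[v] = level[u] + 1
                    queue[qt] = v
                    qt += 1
        if level[t] < 0:
            break
        for i in range(num_nodes):
            iters[i] = adj_ptr[i]
        # DFS blocking flow
        u = s
        depth = 0
        while True:
            if u == t:
                bottleneck = np.inf
                for d in range(depth):
                    if res[path[d]] < bottleneck:
                        bottleneck = res[path[d]]
                for d in range(depth):
                    a = path[d]
                    res[a] -= bottleneck
                    res[a ^ 1] += bottleneck
                total += bottleneck
                # retreat to the first saturated arc on the path
                d0 = 0
                while d0 < depth and res[path[d0]] > _EPS:
                    d0 += 1
                depth = d0
                u = s if depth == 0 else arc_to[path[depth - 1]]
                continue
            advanced = False
            while iters[u] < adj_ptr[u + 1]:
                a = adj_idx[iters[u]]
                v = arc_to[a]
                if res[a] > _EPS and level[v] == level[u] + 1:
                    path[depth] = a
                    depth += 1
                    u = v
                    advanced = True
                    break
                iters[u] += 1
            if not advanced:
                level[u] = -1  # dead end; prune
                if depth == 0:
                    break
                depth -= 1
                u = s if depth == 0 else arc_to[path[depth - 1]]
                iters[u] += 1
    return total


@njit(cache=True)
def _source_side(num_nodes, s, arc_to, res, adj_ptr, adj_idx):  # pragma: no cover
    """Nodes reachable from s in the residual graph: the minimal min cut."""
    seen = np.zeros(num_nodes, np.bool_)
    queue = np.empty(num_nodes, np.int64)
    seen[s] = True
    qh, qt = 0, 1
    queue[0] = s
    while qh < qt:
        u = queue[qh]
        qh += 1
        for k in range(adj_ptr[u], adj_ptr[u + 1]):
            a = adj_idx[k]
            v = arc_to[a]
            if res[a] > _EPS and not seen[v]:
                seen[v] = True
                queue[qt] = v
                qt += 1
    return seen


class FlowNetwork:
    """Reusable s-t flow network over a fixed arc structure.

    Capacities may change between solves (the parametric solver rescales
    the source arcs); the arc structure is built once.
    """

    def __init__(self, num_nodes: int, arc_from: np.ndarray, arc_to: np.ndarray):
        assert len(arc_from) % 2 == 0, "arcs must come in forward/reverse pairs"
        self.num_nodes = num_nodes
        self.arc_to = np.asarray(arc_to, dtype=np.int64)
        order = np.argsort(arc_from, kind="stable")
        self.adj_idx = order.astype(np.int64)
        self.adj_ptr = np.searchsorted(
            arc_from[order], np.arange(num_nodes + 1)
        ).astype(np.int64)

    def min_cut(self, capacities: np.ndarray, s: int, t: int) -> tuple[float, np.ndarray]:
        """Return (max-flow value, minimal source side as a bool mask)."""
        res = np.asarray(capacities, dtype=np.float64).copy()
        value = _max_flow(
            self.num_nodes, s, t, self.arc_to, res, self.adj_ptr, self.adj_idx
        )
        side = _source_side(
            self.num_nodes, s, self.arc_to, res, self.adj_ptr, self.adj_idx
        )
        return value, side
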