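"""Shared fixtures and independent brute-force oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pagmix.graph_core import (
    CATEGORICAL,
    CONTINUOUS,
    MixedGraph,
    Variable,
)


def make_dag(names, edges, categorical=()):
    """Small DAG helper: names list, (parent, child) edges."""
    cats = set(categorical)
    g = MixedGraph(
        [
            Variable(n, CATEGORICAL, ("0", "1", "2")) if n in cats else Variable(n)
            for n in names
        ]
    )
    for p, c in edges:
        g.add_directed_edge(p, c)
    return g


def random_dag_edges(n_nodes: int, p_edge: float, rng: np.random.Generator):
    """Random DAG edge list under the identity topological order."""
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            edges.append((f"N{i}", f"N{j}"))
    return [f"N{i}" for i in range(n_nodes)], edges


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the package implementations)
# ---------------------------------------------------------------------------


def bf_is_ancestor(edges, a, b):
    """Transitive closure by exhaustive DFS over the directed edge list."""
    children = {}
    for p, c in edges:
        children.setdefault(p, []).append(c)
    stack = list(children.get(a, []))
    seen = set()
    while stack:
        n = stack.pop()
        if n == b:
            return True
        if n in seen:
            continue
        seen.add(n)
        stack.extend(children.get(n, []))
    return False


def bf_d_separated(edges, nodes, x, y, s):
    """Enumerate every simple path and apply the per-path blocking rule."""
    s = set(s)
    adj = {n: set() for n in nodes}
    directed = set(edges)
    for p, c in edges:
        adj[p].add(c)
        adj[c].add(p)

    def open_path(path):
        for i in range(1, len(path) - 1):
            prev, mid, nxt = path[i - 1], path[i], path[i + 1]
            collider = (prev, mid) in directed and (nxt, mid) in directed
            if collider:
                if not (mid in s or any(bf_is_ancestor(edges, mid, z) for z in s)):
                    return False
            else:
                if mid in s:
                    return False
        return True

    def paths(path):
        cur = path[-1]
        if cur == y:
            yield path
            return
        for n in adj[cur]:
            if n not in path:
                yield from paths(path + [n])

    return not any(open_path(p) for p in paths([x]))


def bf_moralize_pairs(edges, nodes):
    """Edge set of the moral graph by direct pairwise checking."""
    parents = {n: set() for n in nodes}
    adj = set()
    for p, c in edges:
        parents[c].add(p)
        adj.add(frozenset((p, c)))
    out = set(adj)
    for a, b in itertools.combinations(nodes, 2):
        if any(a in parents[c] and b in parents[c] for c in nodes):
            out.add(frozenset((a, b)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
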