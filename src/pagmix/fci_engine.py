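"""Constraint-based search family: FCI-Stable, FCI-MAX, CFCI and hybrids.

Pipeline: level-wise stable skeleton search -> collider orientation (three
modes) -> Possible-D-Sep edge removal -> reorientation with collider retention
-> complete orientation-rule closure.  All iteration orders are name-sorted so
results are independent of variable order; collider decisions are computed
per-triple and merged deterministically, which makes the batch scheduler's
parallel output identical to the serial one.
"""

from __future__ import annotations

import enum
import itertools
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

from .graph_core import Endpoint, MixedGraph, Variable

#: CI test callable signature: (x, y, conditioning set) -> CITestResult
CITest = Callable[[str, str, frozenset], "object"]


class Mode(enum.Enum):
    FCI = "fci"
    FCI_MAX = "fci-max"
    CFCI = "cfci"


class TripleLabel(enum.Enum):
    COLLIDER = "collider"
    NONCOLLIDER = "noncollider"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SearchConfig:
    mode: Mode = Mode.FCI
    alpha: float = 0.05
    depth: int = 3  # max conditioning-set size; -1 = unlimited
    initial_graph: MixedGraph | None = None
    cores: int = 1
    chunk_beta: float = 1.0
    pdsep_depth: int = 3

    def __post_init__(self) -> None:
        if self.depth < -1:
            raise ValueError("depth must be >= -1")
        if self.cores < 1:
            raise ValueError("cores must be >= 1")
        if self.chunk_beta <= 0:
            raise ValueError("chunk_beta must be positive")


class SepsetMap:
    """Mapping from unordered variable pairs to (separating set, p-value)."""

    def __init__(self) -> None:
        self._entries: dict[frozenset, tuple[tuple[str, ...], float]] = {}

    def record(self, x: str, y: str, sepset: Iterable[str], pvalue: float) -> None:
        self._entries[frozenset((x, y))] = (tuple(sorted(sepset)), float(pvalue))

    def get(self, x: str, y: str) -> tuple[tuple[str, ...], float] | None:
        return self._entries.get(frozenset((x, y)))

    def contains(self, x: str, y: str) -> bool:
        return frozenset((x, y)) in self._entries

    def pairs(self) -> list[frozenset]:
        return sorted(self._entries, key=sorted)

    def __len__(self) -> int:
        return len(self._entries)


def _subset_sizes(limit: int, depth: int) -> range:
    top = limit if depth == -1 else min(depth, limit)
    return range(top + 1)


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------


def complete_graph(variables: Sequence[Variable]) -> MixedGraph:
    g = MixedGraph(variables)
    for a, b in itertools.combinations(g.node_names, 2):
        g.add_edge(a, b)
    return g


def stable_skeleton(
    variables: Sequence[Variable],
    cfg: SearchConfig,
    test: CITest,
) -> tuple[MixedGraph, SepsetMap]:
    """Order-independent PC-style adjacency search.

    Adjacency sets are frozen at the start of each conditioning-set size level
    and removals applied only at the end of the level, so the output does not
    depend on the order edges are visited.
    """
    if cfg.initial_graph is not None:
        g = MixedGraph(variables)
        init = cfg.initial_graph
        for a, b in init.edges():
            g.add_edge(a, b)
    else:
        g = complete_graph(variables)
    sepsets = SepsetMap()

    level = 0
    while True:
        frozen_adj = {n: g.adjacent(n) for n in g.node_names}
        if cfg.depth != -1 and level > cfg.depth:
            break
        if all(len(frozen_adj[n]) - 1 < level for n in g.node_names):
            break
        removals: list[tuple[str, str, tuple[str, ...], float]] = []
        for x, y in g.edges():
            found = None
            seen: set[frozenset] = set()
            for side, other in ((x, y), (y, x)):
                cands = [v for v in frozen_adj[side] if v != other]
                if len(cands) < level:
                    continue
                for subset in itertools.combinations(cands, level):
                    key = frozenset(subset)
                    if key in seen:
                        continue
                    seen.add(key)
                    res = test(x, y, frozenset(subset))
                    if res.independent:
                        found = (x, y, subset, res.pvalue)
                        break
                if found:
                    break
            if found:
                removals.append(found)
        for x, y, subset, pvalue in removals:
            g.remove_edge(x, y)
            sepsets.record(x, y, subset, pvalue)
        level += 1
    return g, sepsets


# ---------------------------------------------------------------------------
# separating-set searches for orientation
# ---------------------------------------------------------------------------


def _candidate_subsets(
    g: MixedGraph, x: str, z: str, depth: int
) -> list[tuple[str, ...]]:
    """All subsets (up to depth) of Adjacent(x)\\{z} and Adjacent(z)\\{x}."""
    seen: set[frozenset] = set()
    out: list[tuple[str, ...]] = []
    for side, other in ((x, z), (z, x)):
        cands = [v for v in g.adjacent(side) if v != other]
        for size in _subset_sizes(len(cands), depth):
            for subset in itertools.combinations(cands, size):
                key = frozenset(subset)
                if key not in seen:
                    seen.add(key)
                    out.append(subset)
    return out


def max_p_sepset(
    x: str,
    z: str,
    g: MixedGraph,
    cfg: SearchConfig,
    test: CITest,
    sepsets: SepsetMap | None = None,
) -> tuple[tuple[str, ...], float, bool]:
    """Subset of the pair's adjacencies with the maximal CI-test p-value.

    The recorded first-found separating set (if any) always joins the
    candidate lattice — edges removed at an earlier level may have been
    separated by nodes that are no longer adjacent.  Ties break towards the
    smaller set, then lexicographic member order.  Returns (sepset, pvalue,
    separates) where ``separates`` says whether the best p-value actually
    exceeds alpha.
    """
    candidates = _candidate_subsets(g, x, z, cfg.depth)
    if sepsets is not None:
        rec = sepsets.get(x, z)
        if rec is not None and rec[0] not in candidates:
            candidates.append(rec[0])
    best: tuple[float, int, tuple[str, ...]] | None = None
    for subset in candidates:
        res = test(x, z, frozenset(subset))
        key = (-res.pvalue, len(subset), subset)
        if best is None or key < best:
            best = key
    assert best is not None  # empty set is always a candidate
    pvalue = -best[0]
    return best[2], pvalue, pvalue > cfg.alpha


def _separating_subsets(
    x: str, z: str, g: MixedGraph, cfg: SearchConfig, test: CITest
) -> list[tuple[str, ...]]:
    """All candidate subsets that render x and z independent (CFCI search)."""
    return [
        subset
        for subset in _candidate_subsets(g, x, z, cfg.depth)
        if test(x, z, frozenset(subset)).independent
    ]


# ---------------------------------------------------------------------------
# collider orientation
# ---------------------------------------------------------------------------


def unshielded_triples(g: MixedGraph) -> list[tuple[str, str, str]]:
    """All (x, y, z) with x-y, y-z adjacent, x-z not, x < z; name-sorted."""
    out = []
    for y in g.node_names:
        neigh = g.adjacent(y)
        for x, z in itertools.combinations(neigh, 2):
            if not g.is_adjacent(x, z):
                out.append((x, y, z))
    out.sort()
    return out


def classify_triple(
    triple: tuple[str, str, str],
    g: MixedGraph,
    sepsets: SepsetMap,
    cfg: SearchConfig,
    test: CITest,
) -> TripleLabel:
    """Mode-dependent unshielded-triple classification."""
    x, y, z = triple
    if cfg.mode is Mode.FCI:
        rec = sepsets.get(x, z)
        if rec is None:
            # pair was never separated by us (e.g. missing from the initial
            # graph): no sepset evidence, leave unoriented
            return TripleLabel.AMBIGUOUS
        return TripleLabel.COLLIDER if y not in rec[0] else TripleLabel.NONCOLLIDER
    if cfg.mode is Mode.FCI_MAX:
        sepset, _, separates = max_p_sepset(x, z, g, cfg, test, sepsets)
        if not separates:
            return TripleLabel.AMBIGUOUS
        return TripleLabel.COLLIDER if y not in sepset else TripleLabel.NONCOLLIDER
    # CFCI: y in none of the separating sets -> collider; in all -> noncollider
    seps = _separating_subsets(x, z, g, cfg, test)
    if not seps:
        return TripleLabel.AMBIGUOUS
    n_with = sum(1 for s in seps if y in s)
    if n_with == 0:
        return TripleLabel.COLLIDER
    if n_with == len(seps):
        return TripleLabel.NONCOLLIDER
    return TripleLabel.AMBIGUOUS


def partition_collider_jobs(
    colliders: Sequence[tuple[str, str, str]],
    g: MixedGraph,
    cores: int,
    beta: float,
) -> list[list[tuple[str, str, str]]]:
    """Recursively bisect the collider list into balanced job batches.

    A batch is subdivided while the summed adjacency load of its triples,
    sum(|Adjacent(X)| + |Adjacent(Z)|), exceeds the chunk size |E| * beta /
    cores.  Batches partition the input exactly and preserve order.
    """
    if cores < 1 or beta <= 0:
        raise ValueError("cores >= 1 and beta > 0 required")
    chunk = g.n_edges * beta / cores

    def load(t: tuple[str, str, str]) -> int:
        return g.degree(t[0]) + g.degree(t[2])

    def split(batch: list[tuple[str, str, str]]) -> list[list[tuple[str, str, str]]]:
        if len(batch) <= 1 or sum(load(t) for t in batch) <= chunk:
            return [batch]
        mid = len(batch) // 2
        return split(batch[:mid]) + split(batch[mid:])

    batch = list(colliders)
    if not batch:
        return []
    return split(batch)


def classify_triples(
    triples: Sequence[tuple[str, str, str]],
    g: MixedGraph,
    sepsets: SepsetMap,
    cfg: SearchConfig,
    test: CITest,
) -> dict[tuple[str, str, str], TripleLabel]:
    """Classify many triples, batched per the job scheduler; merge is sorted."""
    batches = partition_collider_jobs(triples, g, cfg.cores, cfg.chunk_beta)

    def work(batch: list[tuple[str, str, str]]):
        return [(t, classify_triple(t, g, sepsets, cfg, test)) for t in batch]

    results: dict[tuple[str, str, str], TripleLabel] = {}
    if cfg.cores > 1 and len(batches) > 1:
        with ThreadPoolExecutor(max_workers=cfg.cores) as pool:
            chunks = list(pool.map(work, batches))
    else:
        chunks = [work(b) for b in batches]
    for chunk in chunks:
        for t, label in chunk:
            results[t] = label
    return results


def orient_colliders(
    g: MixedGraph,
    sepsets: SepsetMap,
    cfg: SearchConfig,
    test: CITest,
    labels: dict[tuple[str, str, str], TripleLabel] | None = None,
) -> dict[tuple[str, str, str], TripleLabel]:
    """Classify all unshielded triples and add arrowheads for colliders.

    Returns the per-triple labels (used for CFCI's ambiguity bookkeeping and
    for the collider-retention optimization).
    """
    triples = unshielded_triples(g)
    if labels is None:
        labels = classify_triples(triples, g, sepsets, cfg, test)
    for x, y, z in sorted(t for t in triples if labels.get(t) is TripleLabel.COLLIDER):
        g.set_endpoint(x, y, Endpoint.ARROW)
        g.set_endpoint(z, y, Endpoint.ARROW)
    return labels


# ---------------------------------------------------------------------------
# Possible-D-Sep
# ---------------------------------------------------------------------------


def possible_dsep(g: MixedGraph, x: str, y: str | None = None) -> set[str]:
    """Possible-D-SEP(x): nodes reachable from x along paths on which every
    non-endpoint node is a collider on the path or part of a triangle with its
    path neighbours."""
    reachable: set[str] = set()
    queue: deque[tuple[str, str]] = deque()
    visited: set[tuple[str, str]] = set()
    for n in g.adjacent(x):
        queue.append((x, n))
        visited.add((x, n))
    while queue:
        prev, cur = queue.popleft()
        reachable.add(cur)
        for nxt in g.adjacent(cur):
            if nxt == prev or (cur, nxt) in visited:
                continue
            collider = (
                g.endpoint(prev, cur) is Endpoint.ARROW
                and g.endpoint(nxt, cur) is Endpoint.ARROW
            )
            triangle = g.is_adjacent(prev, nxt)
            if collider or triangle:
                visited.add((cur, nxt))
                queue.append((cur, nxt))
    reachable.discard(x)
    if y is not None:
        reachable.discard(y)
    return reachable


def pdsep_phase(
    g: MixedGraph,
    cfg: SearchConfig,
    test: CITest,
    sepsets: SepsetMap,
) -> set[str]:
    """Test remaining edges against subsets of their Possible-D-Sep sets.

    Removes newly separated edges in place, records their sepsets, and returns
    the set of nodes whose adjacencies changed.
    """
    changed: set[str] = set()
    removals: list[tuple[str, str, tuple[str, ...], float]] = []
    for x, y in g.edges():
        found = None
        seen: set[frozenset] = set()
        for side, other in ((x, y), (y, x)):
            pds = sorted(possible_dsep(g, side, other) - {x, y})
            for size in _subset_sizes(len(pds), cfg.pdsep_depth):
                if size == 0:
                    continue  # size-0 was tested during the skeleton phase
                for subset in itertools.combinations(pds, size):
                    key = frozenset(subset)
                    if key in seen:
                        continue
                    seen.add(key)
                    res = test(x, y, frozenset(subset))
                    if res.independent:
                        found = (x, y, subset, res.pvalue)
                        break
                if found:
                    break
            if found:
                break
        if found:
            removals.append(found)
    for x, y, subset, pvalue in removals:
        g.remove_edge(x, y)
        sepsets.record(x, y, subset, pvalue)
        changed.update((x, y))
    return changed


# ---------------------------------------------------------------------------
# orientation rules (Zhang's complete rule set)
# ---------------------------------------------------------------------------


def _is_pd_edge(g: MixedGraph, u: str, v: str) -> bool:
    """Edge u-v traversable u -> v on a potentially directed path."""
    return g.endpoint(v, u) is not Endpoint.ARROW and g.endpoint(u, v) is not Endpoint.TAIL


def _uncovered_path_exists(
    g: MixedGraph,
    a: str,
    b: str,
    edge_ok: Callable[[str, str], bool],
    first_not: str | None = None,
    first_is: str | None = None,
    min_len: int = 2,
) -> bool:
    """DFS for an uncovered path a..b whose every edge satisfies ``edge_ok``.

    Uncovered: consecutive path nodes (i-1, i+1) are non-adjacent.  The first
    intermediate node can be pinned (``first_is``) or excluded (``first_not``).
    """

    def dfs(path: list[str]) -> bool:
        cur = path[-1]
        for nxt in g.adjacent(cur):
            if nxt in path:
                continue
            if len(path) == 1:
                if first_not is not None and nxt == first_not:
                    continue
                if first_is is not None and nxt != first_is:
                    continue
            if not edge_ok(cur, nxt):
                continue
            if len(path) >= 2 and g.is_adjacent(path[-2], nxt):
                continue  # covered triple
            if nxt == b:
                if len(path) >= min_len:
                    return True
                continue
            if dfs(path + [nxt]):
                return True
        return False

    return dfs([a])


def _rule_r1(g: MixedGraph) -> bool:
    changed = False
    for b in g.node_names:
        for a in g.adjacent(b):
            if g.endpoint(a, b) is not Endpoint.ARROW:
                continue
            for c in g.adjacent(b):
                if c == a or g.is_adjacent(a, c):
                    continue
                if g.endpoint(c, b) is Endpoint.CIRCLE:
                    g.set_endpoint(c, b, Endpoint.TAIL)
                    g.set_endpoint(b, c, Endpoint.ARROW)
                    changed = True
    return changed


def _rule_r2(g: MixedGraph) -> bool:
    changed = False
    for a in g.node_names:
        for c in g.adjacent(a):
            if g.endpoint(a, c) is not Endpoint.CIRCLE:
                continue
            for b in g.adjacent(a):
                if b == c or not g.is_adjacent(b, c):
                    continue
                chain1 = (
                    g.is_directed_edge(a, b) and g.endpoint(b, c) is Endpoint.ARROW
                )
                chain2 = (
                    g.endpoint(a, b) is Endpoint.ARROW and g.is_directed_edge(b, c)
                )
                if chain1 or chain2:
                    g.set_endpoint(a, c, Endpoint.ARROW)
                    changed = True
                    break
    return changed


def _rule_r3(g: MixedGraph) -> bool:
    changed = False
    for b in g.node_names:
        into_b = [a for a in g.adjacent(b) if g.endpoint(a, b) is Endpoint.ARROW]
        circ_b = [d for d in g.adjacent(b) if g.endpoint(d, b) is Endpoint.CIRCLE]
        for a, c in itertools.combinations(into_b, 2):
            if g.is_adjacent(a, c):
                continue
            for d in circ_b:
                if d in (a, c):
                    continue
                if (
                    g.endpoint(a, d) is Endpoint.CIRCLE
                    and g.endpoint(c, d) is Endpoint.CIRCLE
                ):
                    g.set_endpoint(d, b, Endpoint.ARROW)
                    changed = True
                    break
    return changed


def _rule_r4(g: MixedGraph, sepsets: SepsetMap) -> bool:
    """Discriminating-path rule."""
    changed = False
    for b in g.node_names:
        for c in g.adjacent(b):
            if g.endpoint(c, b) is not Endpoint.CIRCLE:
                continue
            # candidates for the path node next to b: a <-> b with a -> c
            for a in g.adjacent(b):
                if a == c or not g.is_adjacent(a, c):
                    continue
                if g.endpoint(b, a) is not Endpoint.ARROW:
                    continue
                if g.endpoint(a, b) is not Endpoint.ARROW:
                    continue
                if not g.is_directed_edge(a, c):
                    continue
                d = _find_discriminating_source(g, b, c, a)
                if d is None:
                    continue
                rec = sepsets.get(d, c)
                if rec is None:
                    continue
                if b in rec[0]:
                    g.set_endpoint(c, b, Endpoint.TAIL)
                    g.set_endpoint(b, c, Endpoint.ARROW)
                else:
                    g.set_endpoint(a, b, Endpoint.ARROW)
                    g.set_endpoint(b, a, Endpoint.ARROW)
                    g.set_endpoint(b, c, Endpoint.ARROW)
                    g.set_endpoint(c, b, Endpoint.ARROW)
                changed = True
                if g.endpoint(c, b) is not Endpoint.CIRCLE:
                    break
            if changed:
                break
        if changed:
            break
    return changed


def _find_discriminating_source(
    g: MixedGraph, b: str, c: str, a: str
) -> str | None:
    """Search backwards from ``a`` for the source D of a discriminating path
    <D, ..., a, b, c> for b: every node between D and b is a collider on the
    path and a parent of c; D is not adjacent to c."""

    def dfs(tip: str, path: set[str]) -> str | None:
        for m in g.adjacent(tip):
            if m in path or m == c:
                continue
            if g.endpoint(m, tip) is not Endpoint.ARROW:
                continue  # tip must be a collider on the path
            if not g.is_adjacent(m, c):
                return m
            if g.endpoint(tip, m) is Endpoint.ARROW and g.is_directed_edge(m, c):
                found = dfs(m, path | {m})
                if found is not None:
                    return found
        return None

    return dfs(a, {a, b, c})


def _rule_r5(g: MixedGraph) -> bool:
    changed = False
    for a, b in g.edges():
        if (
            g.endpoint(a, b) is not Endpoint.CIRCLE
            or g.endpoint(b, a) is not Endpoint.CIRCLE
        ):
            continue

        def circle_edge(u: str, v: str) -> bool:
            return (
                g.endpoint(u, v) is Endpoint.CIRCLE
                and g.endpoint(v, u) is Endpoint.CIRCLE
            )

        # uncovered circle path a..b avoiding the direct edge
        path = _find_uncovered_path(g, a, b, circle_edge, exclude_direct=True)
        if path is not None:
            for u, v in zip(path, path[1:]):
                g.set_endpoint(u, v, Endpoint.TAIL)
                g.set_endpoint(v, u, Endpoint.TAIL)
            g.set_endpoint(a, b, Endpoint.TAIL)
            g.set_endpoint(b, a, Endpoint.TAIL)
            changed = True
    return changed


def _find_uncovered_path(
    g: MixedGraph,
    a: str,
    b: str,
    edge_ok: Callable[[str, str], bool],
    exclude_direct: bool = False,
) -> list[str] | None:
    def dfs(path: list[str]) -> list[str] | None:
        cur = path[-1]
        for nxt in g.adjacent(cur):
            if nxt in path:
                continue
            if exclude_direct and len(path) == 1 and nxt == b:
                continue
            if not edge_ok(cur, nxt):
                continue
            if len(path) >= 2 and g.is_adjacent(path[-2], nxt):
                continue
            if nxt == b:
                # need >= 2 intermediates, with the first non-adjacent to b
                # and the last non-adjacent to a
                if (
                    len(path) >= 3
                    and not g.is_adjacent(path[1], b)
                    and not g.is_adjacent(path[-1], a)
                ):
                    return path + [nxt]
                continue
            found = dfs(path + [nxt])
            if found is not None:
                return found
        return None

    return dfs([a])


def _rule_r6(g: MixedGraph) -> bool:
    changed = False
    for b in g.node_names:
        has_undirected = any(
            g.endpoint(a, b) is Endpoint.TAIL and g.endpoint(b, a) is Endpoint.TAIL
            for a in g.adjacent(b)
        )
        if not has_undirected:
            continue
        for c in g.adjacent(b):
            if g.endpoint(c, b) is Endpoint.CIRCLE:
                g.set_endpoint(c, b, Endpoint.TAIL)
                changed = True
    return changed


def _rule_r7(g: MixedGraph) -> bool:
    changed = False
    for b in g.node_names:
        for a in g.adjacent(b):
            if not (
                g.endpoint(b, a) is Endpoint.TAIL
                and g.endpoint(a, b) is Endpoint.CIRCLE
            ):
                continue
            for c in g.adjacent(b):
                if c == a or g.is_adjacent(a, c):
                    continue
                if g.endpoint(c, b) is Endpoint.CIRCLE:
                    g.set_endpoint(c, b, Endpoint.TAIL)
                    changed = True
    return changed


def _rule_r8(g: MixedGraph) -> bool:
    changed = False
    for a in g.node_names:
        for c in g.adjacent(a):
            if not (
                g.endpoint(a, c) is Endpoint.ARROW
                and g.endpoint(c, a) is Endpoint.CIRCLE
            ):
                continue
            for b in g.adjacent(a):
                if b == c or not g.is_adjacent(b, c):
                    continue
                a_to_b = g.is_directed_edge(a, b) or (
                    g.endpoint(b, a) is Endpoint.TAIL
                    and g.endpoint(a, b) is Endpoint.CIRCLE
                )
                if a_to_b and g.is_directed_edge(b, c):
                    g.set_endpoint(c, a, Endpoint.TAIL)
                    changed = True
                    break
    return changed


def _rule_r9(g: MixedGraph) -> bool:
    changed = False
    for a in g.node_names:
        for c in g.adjacent(a):
            if not (
                g.endpoint(a, c) is Endpoint.ARROW
                and g.endpoint(c, a) is Endpoint.CIRCLE
            ):
                continue
            found = False
            for mu in g.adjacent(a):
                if mu == c or g.is_adjacent(mu, c):
                    continue
                if not _is_pd_edge(g, a, mu):
                    continue
                if _uncovered_path_exists(
                    g, a, c, lambda u, v: _is_pd_edge(g, u, v), first_is=mu
                ):
                    found = True
                    break
            if found:
                g.set_endpoint(c, a, Endpoint.TAIL)
                changed = True
    return changed


def _rule_r10(g: MixedGraph) -> bool:
    changed = False
    for c in g.node_names:
        parents = [b for b in g.adjacent(c) if g.is_directed_edge(b, c)]
        if len(parents) < 2:
            continue
        for a in g.adjacent(c):
            if not (
                g.endpoint(a, c) is Endpoint.ARROW
                and g.endpoint(c, a) is Endpoint.CIRCLE
            ):
                continue
            if _r10_applies(g, a, c, parents):
                g.set_endpoint(c, a, Endpoint.TAIL)
                changed = True
    return changed


def _r10_applies(g: MixedGraph, a: str, c: str, parents: list[str]) -> bool:
    for b, d in itertools.combinations(parents, 2):
        if a in (b, d):
            continue
        for mu in g.adjacent(a):
            if not _is_pd_edge(g, a, mu):
                continue
            p1 = (mu == b) or _uncovered_path_exists(
                g, a, b, lambda u, v: _is_pd_edge(g, u, v), first_is=mu
            )
            if not p1:
                continue
            for om in g.adjacent(a):
                if om == mu or g.is_adjacent(mu, om):
                    continue
                if not _is_pd_edge(g, a, om):
                    continue
                p2 = (om == d) or _uncovered_path_exists(
                    g, a, d, lambda u, v: _is_pd_edge(g, u, v), first_is=om
                )
                if p2:
                    return True
    return False


def apply_orientation_rules(
    g: MixedGraph,
    sepsets: SepsetMap,
    ambiguous: frozenset = frozenset(),
    complete: bool = True,
) -> None:
    """Apply Zhang's orientation rules R1-R10 to closure, in place.

    Triples recorded as ambiguous (CFCI) are skipped by R1, which presumes a
    definite non-collider.
    """

    def r1_guarded() -> bool:
        changed = False
        for b in g.node_names:
            for a in g.adjacent(b):
                if g.endpoint(a, b) is not Endpoint.ARROW:
                    continue
                for c in g.adjacent(b):
                    if c == a or g.is_adjacent(a, c):
                        continue
                    t = (min(a, c), b, max(a, c))
                    if t in ambiguous:
                        continue
                    if g.endpoint(c, b) is Endpoint.CIRCLE:
                        g.set_endpoint(c, b, Endpoint.TAIL)
                        g.set_endpoint(b, c, Endpoint.ARROW)
                        changed = True
        return changed

    rules: list[Callable[[], bool]] = [
        r1_guarded,
        lambda: _rule_r2(g),
        lambda: _rule_r3(g),
        lambda: _rule_r4(g, sepsets),
    ]
    if complete:
        rules += [
            lambda: _rule_r5(g),
            lambda: _rule_r6(g),
            lambda: _rule_r7(g),
            lambda: _rule_r8(g),
            lambda: _rule_r9(g),
            lambda: _rule_r10(g),
        ]
    while True:
        if not any(rule() for rule in rules):
            break


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def reorient_and_finalize(
    g: MixedGraph,
    sepsets: SepsetMap,
    cfg: SearchConfig,
    test: CITest,
    prev_labels: dict[tuple[str, str, str], TripleLabel],
    pre_adj: dict[str, list[str]],
) -> MixedGraph:
    """Reset marks to circles, re-orient colliders (retaining decisions for
    triples whose endpoint adjacencies survived Possible-D-Sep unchanged) and
    close under the orientation rules."""
    for a, b in g.edges():
        g.set_endpoint(a, b, Endpoint.CIRCLE)
        g.set_endpoint(b, a, Endpoint.CIRCLE)

    triples = unshielded_triples(g)
    retained: dict[tuple[str, str, str], TripleLabel] = {}
    fresh: list[tuple[str, str, str]] = []
    for t in triples:
        x, _, z = t
        if (
            t in prev_labels
            and g.adjacent(x) == pre_adj.get(x)
            and g.adjacent(z) == pre_adj.get(z)
        ):
            retained[t] = prev_labels[t]
        else:
            fresh.append(t)
    labels = dict(retained)
    labels.update(classify_triples(fresh, g, sepsets, cfg, test))
    orient_colliders(g, sepsets, cfg, test, labels=labels)
    ambiguous = frozenset(
        t for t, lab in labels.items() if lab is TripleLabel.AMBIGUOUS
    )
    apply_orientation_rules(g, sepsets, ambiguous)
    return g


@dataclass
class FciResult:
    pag: MixedGraph
    sepsets: SepsetMap
    labels: dict[tuple[str, str, str], TripleLabel] = field(default_factory=dict)


def run_detailed(
    variables: Sequence[Variable],
    cfg: SearchConfig,
    test: CITest,
) -> FciResult:
    """Full pipeline returning the PAG plus sepsets and triple labels."""
    g, sepsets = stable_skeleton(variables, cfg, test)
    first_labels = orient_colliders(g, sepsets, cfg, test)
    pre_adj = {n: g.adjacent(n) for n in g.node_names}
    pdsep_phase(g, cfg, test, sepsets)
    reorient_and_finalize(g, sepsets, cfg, test, first_labels, pre_adj)
    final_triples = set(unshielded_triples(g))
    labels = {t: lab for t, lab in first_labels.items() if t in final_triples}
    return FciResult(pag=g, sepsets=sepsets, labels=labels)


def run(
    variables: Sequence[Variable],
    cfg: SearchConfig,
    test: CITest,
) -> MixedGraph:
    """stable_skeleton -> orient_colliders -> pdsep_phase -> reorient_and_finalize."""
    return run_detailed(variables, cfg, test).pag
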