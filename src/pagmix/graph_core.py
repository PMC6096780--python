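"""Graph and dataset data model shared by all search algorithms.

Provides endpoint-labelled mixed graphs able to represent DAGs, undirected
skeletons and partial ancestral graphs (PAGs), ancestry and d-separation
queries on DAG views, moralization, and plain-text I/O for graphs and for
mixed continuous/categorical datasets.

Endpoint convention: for an edge between ``a`` and ``b`` the graph stores one
mark *at each end*; ``endpoint(a, b)`` is the mark at ``b`` on that edge (the
mark "seen when looking from a towards b"), mirroring TETRAD's
``getEndpoint(from, to)``.
"""

from __future__ import annotations

import enum
import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class GraphStructureError(ValueError):
    """Raised when a graph does not satisfy the view required by an operation."""


class GraphParseError(ValueError):
    """Raised on malformed graph files; carries the offending line number."""


class Endpoint(enum.Enum):
    """Mark at one end of an edge."""

    TAIL = "-"
    ARROW = ">"
    CIRCLE = "o"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Endpoint.{self.name}"


@dataclass(frozen=True)
class Variable:
    """A named column: continuous, or categorical with ordered category labels."""

    name: str
    vartype: str = CONTINUOUS
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.vartype not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown vartype {self.vartype!r}")
        if self.vartype == CATEGORICAL and len(self.categories) < 2:
            raise ValueError(
                f"categorical variable {self.name!r} needs >= 2 categories"
            )
        if self.vartype == CONTINUOUS and self.categories:
            raise ValueError(f"continuous variable {self.name!r} has categories")

    @property
    def is_categorical(self) -> bool:
        return self.vartype == CATEGORICAL

    @property
    def n_categories(self) -> int:
        return len(self.categories)


def _check_unique_names(variables: Sequence[Variable]) -> None:
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate variable names: {dupes}")


class MixedGraph:
    """Endpoint-labelled graph over :class:`Variable` nodes.

    One structure serves three views: DAGs (every edge TAIL->ARROW, acyclic),
    undirected skeletons (every edge CIRCLE-CIRCLE), and PAGs (arbitrary mark
    combinations).  Nodes are addressed by name; all iteration orders are
    lexicographic so downstream algorithms are independent of insertion order.
    """

    def __init__(self, variables: Iterable[Variable] = ()) -> None:
        self._vars: dict[str, Variable] = {}
        self._adj: dict[str, dict[str, Endpoint]] = {}
        for v in variables:
            self.add_node(v)

    # ------------------------------------------------------------------ nodes
    def add_node(self, var: Variable) -> None:
        if var.name in self._vars:
            raise ValueError(f"duplicate node {var.name!r}")
        self._vars[var.name] = var
        self._adj[var.name] = {}

    @property
    def node_names(self) -> list[str]:
        return sorted(self._vars)

    @property
    def variables(self) -> list[Variable]:
        return [self._vars[n] for n in self.node_names]

    def variable(self, name: str) -> Variable:
        return self._vars[name]

    def __contains__(self, name: str) -> bool:
        return name in self._vars

    def __len__(self) -> int:
        return len(self._vars)

    # ------------------------------------------------------------------ edges
    def add_edge(
        self,
        a: str,
        b: str,
        mark_at_a: Endpoint = Endpoint.CIRCLE,
        mark_at_b: Endpoint = Endpoint.CIRCLE,
    ) -> None:
        if a == b:
            raise ValueError("self loops not allowed")
        for n in (a, b):
            if n not in self._vars:
                raise KeyError(f"unknown node {n!r}")
        self._adj[a][b] = mark_at_b
        self._adj[b][a] = mark_at_a

    def add_directed_edge(self, parent: str, child: str) -> None:
        self.add_edge(parent, child, Endpoint.TAIL, Endpoint.ARROW)

    def remove_edge(self, a: str, b: str) -> None:
        del self._adj[a][b]
        del self._adj[b][a]

    def is_adjacent(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, {})

    def adjacent(self, a: str) -> list[str]:
        """Neighbours of ``a``, sorted by name."""
        return sorted(self._adj[a])

    def degree(self, a: str) -> int:
        return len(self._adj[a])

    def endpoint(self, a: str, b: str) -> Endpoint | None:
        """Mark at ``b`` on the edge a-b, or None if non-adjacent."""
        return self._adj[a].get(b)

    def set_endpoint(self, a: str, b: str, mark: Endpoint) -> None:
        if b not in self._adj[a]:
            raise KeyError(f"no edge {a!r} - {b!r}")
        self._adj[a][b] = mark

    def edges(self) -> list[tuple[str, str]]:
        """Unordered edge list as (a, b) pairs with a < b, sorted."""
        out = []
        for a in self.node_names:
            for b in self._adj[a]:
                if a < b:
                    out.append((a, b))
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(d) for d in self._adj.values()) // 2

    # ------------------------------------------------------------------ views
    def is_directed_edge(self, parent: str, child: str) -> bool:
        return (
            self._adj.get(parent, {}).get(child) is Endpoint.ARROW
            and self._adj.get(child, {}).get(parent) is Endpoint.TAIL
        )

    def parents(self, node: str) -> list[str]:
        return sorted(n for n in self._adj[node] if self.is_directed_edge(n, node))

    def children(self, node: str) -> list[str]:
        return sorted(n for n in self._adj[node] if self.is_directed_edge(node, n))

    def is_dag_view(self) -> bool:
        for a, b in self.edges():
            if not (self.is_directed_edge(a, b) or self.is_directed_edge(b, a)):
                return False
        return nx.is_directed_acyclic_graph(self.to_digraph(validate=False))

    def to_digraph(self, validate: bool = True) -> nx.DiGraph:
        """DAG view as a networkx DiGraph; requires every edge to be directed."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.node_names)
        for a, b in self.edges():
            if self.is_directed_edge(a, b):
                dg.add_edge(a, b)
            elif self.is_directed_edge(b, a):
                dg.add_edge(b, a)
            elif validate:
                raise GraphStructureError(f"edge {a!r}-{b!r} is not directed")
        if validate and not nx.is_directed_acyclic_graph(dg):
            raise GraphStructureError("graph is cyclic; not a DAG view")
        return dg

    def copy(self) -> "MixedGraph":
        g = MixedGraph(self.variables)
        for a, d in self._adj.items():
            g._adj[a] = dict(d)
        return g

    def subgraph(self, names: Iterable[str]) -> "MixedGraph":
        keep = set(names)
        g = MixedGraph([v for v in self.variables if v.name in keep])
        for a, b in self.edges():
            if a in keep and b in keep:
                g.add_edge(a, b, self.endpoint(b, a), self.endpoint(a, b))
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixedGraph):
            return NotImplemented
        return self._vars == other._vars and self._adj == other._adj

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<MixedGraph {len(self)} nodes, {self.n_edges} edges>"


# ---------------------------------------------------------------------------
# DAG queries
# ---------------------------------------------------------------------------


class DagIndex:
    """Precomputed parent/child maps for fast repeated ancestry/d-sep queries.

    Node sets are held as integer bitmasks so the inner reachability loop is
    cheap even when the d-separation oracle is queried hundreds of thousands
    of times during a Possible-D-Sep phase.
    """

    def __init__(self, g: MixedGraph) -> None:
        if not g.is_dag_view():
            raise GraphStructureError("DagIndex requires a DAG view")
        names = g.node_names
        self._idx = {n: i for i, n in enumerate(names)}
        self._names = names
        self._parents = [0] * len(names)
        self._children = [0] * len(names)
        self.parents: dict[str, list[str]] = {}
        self.children: dict[str, list[str]] = {}
        for n in names:
            self.parents[n] = g.parents(n)
            self.children[n] = g.children(n)
            i = self._idx[n]
            for p in self.parents[n]:
                self._parents[i] |= 1 << self._idx[p]
            for c in self.children[n]:
                self._children[i] |= 1 << self._idx[c]

    def _mask_ancestors(self, mask: int) -> int:
        """Strict-or-self ancestor closure of a node bitmask."""
        seen = 0
        frontier = mask
        while frontier:
            seen |= frontier
            nxt = 0
            f = frontier
            while f:
                low = f & -f
                nxt |= self._parents[low.bit_length() - 1]
                f ^= low
            frontier = nxt & ~seen
        return seen

    def ancestors(self, nodes: Iterable[str]) -> set[str]:
        """All strict-or-self ancestors of the given nodes."""
        mask = 0
        for n in nodes:
            mask |= 1 << self._idx[n]
        closure = self._mask_ancestors(mask)
        return {n for n in self._names if closure >> self._idx[n] & 1}

    def d_separated(self, x: str, y: str, s: Iterable[str]) -> bool:
        """Classic reachability ("Bayes ball") d-separation test."""
        xi, yi = self._idx[x], self._idx[y]
        z = 0
        for n in s:
            z |= 1 << self._idx[n]
        if x == y or z >> xi & 1 or z >> yi & 1:
            raise ValueError("require x != y and x, y not in s")
        anc_z = self._mask_ancestors(z)  # collider opens iff node is in here
        ybit = 1 << yi
        parents, children = self._parents, self._children
        # two visited masks: reached trailing out of the node (tail side) and
        # reached through an arrow into the node
        seen_tail = 1 << xi
        seen_head = 0
        frontier = [(xi, False)]
        while frontier:
            node, via_arrow_in = frontier.pop()
            bit = 1 << node
            in_z = z & bit
            heads = tails = 0
            if via_arrow_in:
                if not in_z:
                    heads = children[node]
                if anc_z & bit:
                    tails = parents[node]
            else:
                if not in_z:
                    heads = children[node]
                    tails = parents[node]
            if (heads | tails) & ybit:
                return False
            heads &= ~seen_head
            tails &= ~seen_tail
            seen_head |= heads
            seen_tail |= tails
            while heads:
                low = heads & -heads
                frontier.append((low.bit_length() - 1, True))
                heads ^= low
            while tails:
                low = tails & -tails
                frontier.append((low.bit_length() - 1, False))
                tails ^= low
        return True


def is_ancestor(g: MixedGraph, a: str, b: str) -> bool:
    """True iff a directed path a -> ... -> b exists in the DAG view of ``g``.

    A node is not its own ancestor.
    """
    dg = g.to_digraph()
    if a == b:
        return False
    return nx.has_path(dg, a, b)


def d_separated(g: MixedGraph, x: str, y: str, s: Iterable[str] = ()) -> bool:
    """Standard d-separation of x and y given s in the DAG view of ``g``."""
    return DagIndex(g).d_separated(x, y, s)


def topological_order(g: MixedGraph) -> list[str]:
    return list(nx.lexicographical_topological_sort(g.to_digraph()))


def moralize(g: MixedGraph) -> MixedGraph:
    """Undirected graph with the DAG's adjacencies plus edges between co-parents."""
    dg = g.to_digraph()
    out = MixedGraph(g.variables)
    for a, b in g.edges():
        out.add_edge(a, b)
    for child in g.node_names:
        pars = sorted(dg.predecessors(child))
        for a, b in itertools.combinations(pars, 2):
            if not out.is_adjacent(a, b):
                out.add_edge(a, b)
    return out


# ---------------------------------------------------------------------------
# Graph file I/O
# ---------------------------------------------------------------------------

_MARK_LEFT = {"o": Endpoint.CIRCLE, "<": Endpoint.ARROW, "-": Endpoint.TAIL}
_MARK_RIGHT = {"o": Endpoint.CIRCLE, ">": Endpoint.ARROW, "-": Endpoint.TAIL}
_LEFT_CHAR = {Endpoint.CIRCLE: "o", Endpoint.ARROW: "<", Endpoint.TAIL: "-"}
_RIGHT_CHAR = {Endpoint.CIRCLE: "o", Endpoint.ARROW: ">", Endpoint.TAIL: "-"}

#: canonical tokens, preferred orientation of asymmetric mark pairs
_CANONICAL_LEFT = {
    (Endpoint.TAIL, Endpoint.TAIL),
    (Endpoint.CIRCLE, Endpoint.CIRCLE),
    (Endpoint.CIRCLE, Endpoint.ARROW),
    (Endpoint.ARROW, Endpoint.ARROW),
    (Endpoint.TAIL, Endpoint.ARROW),
    (Endpoint.TAIL, Endpoint.CIRCLE),
}


def _edge_token(mark_at_a: Endpoint, mark_at_b: Endpoint) -> str:
    return f"{_LEFT_CHAR[mark_at_a]}-{_RIGHT_CHAR[mark_at_b]}"


def parse_edge_token(token: str) -> tuple[Endpoint, Endpoint]:
    """Parse a 3-character edge token into (mark at left node, mark at right)."""
    if len(token) != 3 or token[1] != "-":
        raise ValueError(f"bad edge token {token!r}")
    try:
        return _MARK_LEFT[token[0]], _MARK_RIGHT[token[2]]
    except KeyError:
        raise ValueError(f"bad edge token {token!r}") from None


def write_graph(g: MixedGraph, path) -> None:
    """Write ``g`` in the line-oriented edge-list dialect (see :func:`read_graph`)."""
    lines = ["#nodes"]
    for v in g.variables:
        if v.is_categorical:
            lines.append(f"{v.name}\t{CATEGORICAL}\t{','.join(v.categories)}")
        else:
            lines.append(f"{v.name}\t{CONTINUOUS}")
    lines.append("#edges")
    for a, b in g.edges():
        ma, mb = g.endpoint(b, a), g.endpoint(a, b)
        if (ma, mb) not in _CANONICAL_LEFT:
            a, b, ma, mb = b, a, mb, ma
        lines.append(f"{a} {_edge_token(ma, mb)} {b}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_graph(path) -> MixedGraph:
    """Read a graph written by :func:`write_graph`.

    Format::

        #nodes
        X1<TAB>continuous
        X2<TAB>categorical<TAB>a,b,c
        #edges
        X1 o-> X2
    """
    g = MixedGraph()
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "#nodes":
                section = "nodes"
                continue
            if line == "#edges":
                section = "edges"
                continue
            if section == "nodes":
                parts = line.split("\t")
                try:
                    if parts[1] == CATEGORICAL:
                        g.add_node(
                            Variable(parts[0], CATEGORICAL, tuple(parts[2].split(",")))
                        )
                    elif parts[1] == CONTINUOUS:
                        g.add_node(Variable(parts[0]))
                    else:
                        raise ValueError(f"unknown type {parts[1]!r}")
                except (IndexError, ValueError) as exc:
                    raise GraphParseError(f"line {lineno}: {exc}") from None
            elif section == "edges":
                parts = line.split()
                if len(parts) != 3:
                    raise GraphParseError(f"line {lineno}: expected 'A <mark> B'")
                a, token, b = parts
                try:
                    ma, mb = parse_edge_token(token)
                except ValueError as exc:
                    raise GraphParseError(f"line {lineno}: {exc}") from None
                if a not in g or b not in g:
                    raise GraphParseError(f"line {lineno}: undeclared node in edge")
                g.add_edge(a, b, ma, mb)
            else:
                raise GraphParseError(f"line {lineno}: content before '#nodes' header")
    return g


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


@dataclass
class MixedDataset:
    """Column-typed sample table.

    ``frame`` holds continuous columns as float64 and categorical columns as
    integer category codes into the matching :class:`Variable`'s ``categories``.
    """

    variables: list[Variable]
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique_names(self.variables)
        if list(self.frame.columns) != [v.name for v in self.variables]:
            raise ValueError("frame columns must match variable order")
        if self.frame.isna().any().any():
            raise ValueError("missing cells are not supported")
        for v in self.variables:
            col = self.frame[v.name]
            if v.is_categorical:
                codes = col.to_numpy()
                if codes.size and (codes.min() < 0 or codes.max() >= v.n_categories):
                    raise ValueError(f"invalid category code in column {v.name!r}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def is_categorical(self, name: str) -> bool:
        return self.variable(name).is_categorical

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def drop(self, names: Iterable[str]) -> "MixedDataset":
        gone = set(names)
        keep = [v for v in self.variables if v.name not in gone]
        return MixedDataset(keep, self.frame[[v.name for v in keep]].copy())

    def to_labeled_frame(self) -> pd.DataFrame:
        """Frame with categorical codes replaced by their category labels."""
        out = self.frame.copy()
        for v in self.variables:
            if v.is_categorical:
                labels = np.asarray(v.categories, dtype=object)
                out[v.name] = labels[self.frame[v.name].to_numpy()]
        return out

    def write(self, path, sep: str = "\t") -> None:
        self.to_labeled_frame().to_csv(path, sep=sep, index=False)


def _sorted_labels(values: Iterable) -> list[str]:
    """Category labels in a stable order: numeric if possible, else lexicographic."""
    uniq = list(dict.fromkeys(str(v) for v in values))
    try:
        return sorted(set(uniq), key=float)
    except ValueError:
        return sorted(set(uniq))


def read_dataset(
    path,
    sep: str | None = None,
    categorical_threshold: int = 5,
    type_overrides: dict[str, str] | None = None,
    types_path=None,
) -> MixedDataset:
    """Read a delimited table with header, inferring column types.

    A column is categorical iff it is non-numeric, or integer-valued with at
    most ``categorical_threshold`` distinct values; an explicit override map or
    sidecar file (``name<TAB>{continuous|categorical}`` per line) wins over
    inference.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, header=0, dtype=str, skipinitialspace=True)
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValueError(f"empty cells or ragged rows in column(s) {bad}")
    overrides = dict(type_overrides or {})
    if types_path is not None:
        with open(types_path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    name, typ = line.split("\t")
                    overrides[name] = typ

    variables: list[Variable] = []
    columns: dict[str, np.ndarray] = {}
    for name in raw.columns:
        text = raw[name]
        numeric = pd.to_numeric(text, errors="coerce")
        is_numeric = not numeric.isna().any()
        declared = overrides.get(name)
        if declared == CONTINUOUS:
            if not is_numeric:
                raise ValueError(f"column {name!r} declared continuous but non-numeric")
            categorical = False
        elif declared == CATEGORICAL:
            categorical = True
        elif declared is not None:
            raise ValueError(f"bad type override {declared!r} for column {name!r}")
        else:
            categorical = (not is_numeric) or (
                np.allclose(numeric, numeric.round())
                and numeric.nunique() <= categorical_threshold
            )
        if categorical and text.nunique() < 2 and is_numeric and declared is None:
            categorical = False  # constant numeric column: fall back to continuous
        if categorical:
            labels = _sorted_labels(text)
            index = {lab: i for i, lab in enumerate(labels)}
            columns[name] = np.array([index[str(v)] for v in text], dtype=np.int64)
            variables.append(Variable(name, CATEGORICAL, tuple(labels)))
        else:
            columns[name] = numeric.to_numpy(dtype=np.float64)
            variables.append(Variable(name))
    frame = pd.DataFrame(columns, columns=list(raw.columns))
    return MixedDataset(variables, frame)
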