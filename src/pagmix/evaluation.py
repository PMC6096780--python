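"""PAG-vs-PAG scoring: adjacency and endpoint-orientation precision/recall.

Adjacency counts treat an edge as shared when it appears in both graphs
regardless of marks.  Orientation counts are computed only over shared edges,
one judgement per endpoint, with fractional (half) penalties when the
predicted mark is a circle and a consultation of the data-generating DAG when
the true mark is a circle:

======================  ============  ===========  ===========
true mark at B           pred o        pred >       pred -
======================  ============  ===========  ===========
o                        1 TP          1 TP if not  1 TP if
                                       Anc(B,A)     Anc(B,A)
                                       else 1 FN    else 1 FP
>                        1/2 FP        1 TP         1 FP
-                        1/2 FN        1 FN         1 TP
======================  ============  ===========  ===========

Counts are stratified by the edge's variable types (CC / CD / DD) and pooled
into ALL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import networkx as nx

from .graph_core import Endpoint, GraphStructureError, MixedGraph

STRATA = ("CC", "CD", "DD", "ALL")


@dataclass
class Counts:
    tp: Fraction = Fraction(0)
    fp: Fraction = Fraction(0)
    fn: Fraction = Fraction(0)

    def add(self, tp=0, fp=0, fn=0) -> None:
        self.tp += Fraction(tp)
        self.fp += Fraction(fp)
        self.fn += Fraction(fn)

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return float(self.tp / denom) if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.tp + self.fn
        return float(self.tp / denom) if denom else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


@dataclass
class EvalReport:
    adjacency: dict[str, Counts] = field(
        default_factory=lambda: {s: Counts() for s in STRATA}
    )
    orientation: dict[str, Counts] = field(
        default_factory=lambda: {s: Counts() for s in STRATA}
    )

    def rows(self) -> list[dict]:
        out = []
        for metric, table in (("adjacency", self.adjacency), ("orientation", self.orientation)):
            for stratum in STRATA:
                c = table[stratum]
                out.append(
                    {
                        "stratum": stratum,
                        "metric": metric,
                        "TP": float(c.tp),
                        "FP": float(c.fp),
                        "FN": float(c.fn),
                        "precision": c.precision,
                        "recall": c.recall,
                        "F1": c.f1,
                    }
                )
        return out


def _stratum(g: MixedGraph, a: str, b: str) -> str:
    n_cat = sum(1 for n in (a, b) if g.variable(n).is_categorical)
    return ("CC", "CD", "DD")[n_cat]


def _check_nodes(est: MixedGraph, truth: MixedGraph) -> None:
    if set(est.node_names) != set(truth.node_names):
        raise ValueError("estimated and true PAGs must share a node set")


def adjacency_confusion(est: MixedGraph, truth: MixedGraph) -> dict[str, Counts]:
    """Shared / est-only / truth-only edge counts per variable-type stratum."""
    _check_nodes(est, truth)
    table = {s: Counts() for s in STRATA}
    est_edges = set(map(frozenset, est.edges()))
    true_edges = set(map(frozenset, truth.edges()))
    for pair in est_edges | true_edges:
        a, b = sorted(pair)
        stratum = _stratum(truth, a, b)
        if pair in est_edges and pair in true_edges:
            kw = {"tp": 1}
        elif pair in est_edges:
            kw = {"fp": 1}
        else:
            kw = {"fn": 1}
        table[stratum].add(**kw)
        table["ALL"].add(**kw)
    return table


class _AncestryOracle:
    """is-ancestor queries against the data-generating DAG, cached."""

    def __init__(self, dag: MixedGraph) -> None:
        self._dg = dag.to_digraph()
        self._desc: dict[str, set[str]] = {}

    def __call__(self, a: str, b: str) -> bool:
        if a not in self._desc:
            self._desc[a] = nx.descendants(self._dg, a)
        return b in self._desc[a]


def endpoint_score(
    true_mark: Endpoint,
    pred_mark: Endpoint,
    ancestor_b_a: bool,
) -> tuple[Fraction, Fraction, Fraction]:
    """(TP, FP, FN) increment for one endpoint judgement at B on edge A *-x B."""
    half = Fraction(1, 2)
    one = Fraction(1)
    zero = Fraction(0)
    if true_mark is Endpoint.CIRCLE:
        if pred_mark is Endpoint.CIRCLE:
            return one, zero, zero
        if pred_mark is Endpoint.ARROW:
            return (one, zero, zero) if not ancestor_b_a else (zero, zero, one)
        return (one, zero, zero) if ancestor_b_a else (zero, one, zero)
    if true_mark is Endpoint.ARROW:
        if pred_mark is Endpoint.CIRCLE:
            return zero, half, zero
        if pred_mark is Endpoint.ARROW:
            return one, zero, zero
        return zero, one, zero
    if true_mark is Endpoint.TAIL:
        if pred_mark is Endpoint.CIRCLE:
            return zero, zero, half
        if pred_mark is Endpoint.ARROW:
            return zero, zero, one
        return one, zero, zero
    raise GraphStructureError("NULL endpoint on a shared edge")


def orientation_score(
    est: MixedGraph, truth: MixedGraph, dag: MixedGraph
) -> dict[str, Counts]:
    """Endpoint-orientation confusion over shared edges, per stratum."""
    _check_nodes(est, truth)
    anc = _AncestryOracle(dag)
    table = {s: Counts() for s in STRATA}
    for a, b in truth.edges():
        if not est.is_adjacent(a, b):
            continue
        stratum = _stratum(truth, a, b)
        for far, near in ((a, b), (b, a)):
            # judge the mark at `near` on the edge far *-x near
            tm = truth.endpoint(far, near)
            pm = est.endpoint(far, near)
            if tm is None or pm is None:
                raise GraphStructureError("NULL endpoint on a shared edge")
            tp, fp, fn = endpoint_score(tm, pm, anc(near, far))
            table[stratum].add(tp, fp, fn)
            table["ALL"].add(tp, fp, fn)
    return table


def report(est: MixedGraph, truth: MixedGraph, dag: MixedGraph) -> EvalReport:
    """Assemble adjacency and orientation confusions into one report."""
    return EvalReport(
        adjacency=adjacency_confusion(est, truth),
        orientation=orientation_score(est, truth, dag),
    )


def write_report(rep: EvalReport, path) -> None:
    cols = ["stratum", "metric", "TP", "FP", "FN", "precision", "recall", "F1"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rep.rows():
            fh.write(
                "\t".join(
                    "" if row[c] is None else str(row[c]) for c in cols
                )
                + "\n"
            )
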