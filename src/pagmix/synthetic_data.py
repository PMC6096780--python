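"""Random mixed DAGs, structural-equation sampling and ground-truth PAGs.

Graphs are half continuous / half categorical by default.  Continuous
children receive linear parent contributions plus Gaussian noise; categorical
children receive log-linear contributions to their category probabilities and
are sampled by inverse-CDF against a uniform error draw.  Categorical edge
parameter vectors are forced to be non-monotonic in the category index so the
relationships cannot be captured by treating codes as numeric.  Latent
variables are chosen among nodes with at least two observed children, and the
ground-truth PAG is the oracle-FCI output over the observed nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import fci_engine
from .ci_tests import OracleCITest
from .graph_core import (
    CATEGORICAL,
    CONTINUOUS,
    MixedDataset,
    MixedGraph,
    Variable,
    topological_order,
)

import pandas as pd


@dataclass(frozen=True)
class SimConfig:
    n_nodes: int = 50
    frac_continuous: float = 0.5
    n_categories: int = 3
    edge_count_mean: float = 100.0
    edge_count_sd: float = 30.0
    n_latents: int = 5
    n_samples: int = 1000
    weight_low: float = 0.5
    weight_high: float = 1.5
    noise_sd_low: float = 1.0
    noise_sd_high: float = 2.0
    topology: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_latents < self.n_nodes:
            raise ValueError("need 0 <= n_latents < n_nodes")
        if self.topology not in ("random", "scale_free"):
            raise ValueError("topology must be 'random' or 'scale_free'")
        if not 0.0 <= self.frac_continuous <= 1.0:
            raise ValueError("frac_continuous must lie in [0, 1]")


@dataclass
class ParamDAG:
    """A DAG with edge/node parameters for structural-equation sampling.

    Edge parameters are keyed by (parent, child): a scalar weight for CC
    edges, a length-k vector indexed by the discrete endpoint's category for
    CD edges, and a (k_parent, k_child) matrix for DD edges.
    """

    dag: MixedGraph
    cc_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    cd_params: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    dd_params: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    cont_node: dict[str, float] = field(default_factory=dict)  # noise sd
    disc_node: dict[str, np.ndarray] = field(default_factory=dict)  # baselines


def _node_name(i: int, width: int) -> str:
    return f"X{i:0{width}d}"


def random_dag(cfg: SimConfig, rng: np.random.Generator | None = None) -> MixedGraph:
    """Random DAG under a fixed topological order with a Normal edge count."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_nodes
    max_edges = n * (n - 1) // 2
    n_edges = int(round(rng.normal(cfg.edge_count_mean, cfg.edge_count_sd)))
    n_edges = int(np.clip(n_edges, n - 1, max_edges))

    n_cont = int(round(cfg.frac_continuous * n))
    cont_idx = set(rng.choice(n, size=n_cont, replace=False).tolist())
    width = len(str(n - 1))
    variables = []
    cats = tuple(str(c) for c in range(cfg.n_categories))
    for i in range(n):
        if i in cont_idx:
            variables.append(Variable(_node_name(i, width), CONTINUOUS))
        else:
            variables.append(Variable(_node_name(i, width), CATEGORICAL, cats))

    g = MixedGraph(variables)
    chosen: set[tuple[int, int]] = set()
    if cfg.topology == "random":
        pairs = list(itertools.combinations(range(n), 2))
        take = rng.choice(len(pairs), size=n_edges, replace=False)
        chosen = {pairs[i] for i in take}
    else:  # scale_free: preferential attachment on the target endpoint
        degree = np.ones(n)
        while len(chosen) < n_edges:
            a = int(rng.integers(n))
            probs = degree / degree.sum()
            b = int(rng.choice(n, p=probs))
            if a == b:
                continue
            pair = (min(a, b), max(a, b))
            if pair in chosen:
                continue
            chosen.add(pair)
            degree[a] += 1
            degree[b] += 1
    for i, j in sorted(chosen):
        g.add_directed_edge(variables[i].name, variables[j].name)
    return g


def _is_monotone(vec: np.ndarray) -> bool:
    """Strictly increasing or decreasing in the category index.

    Strictness matters: with three distinct permutations of one 3-vector as
    matrix rows, some row or column always has a weakly monotone (tied)
    pattern, so the weak version admits no valid DD matrix at all.
    """
    d = np.diff(vec)
    return bool(np.all(d > 0) or np.all(d < 0))


def _draw_weight(cfg: SimConfig, rng: np.random.Generator) -> float:
    """Magnitude uniform in [weight_low, weight_high], random sign."""
    w = rng.uniform(cfg.weight_low, cfg.weight_high)
    return float(w if rng.random() < 0.5 else -w)


def _cd_vector(cfg: SimConfig, rng: np.random.Generator, k: int) -> np.ndarray:
    """Zero-sum category vector whose largest element is the drawn magnitude.

    Draw k uniforms, centre to sum zero, rescale so max equals |w|, flip the
    sign for negative weights, then permute until non-monotone.
    """
    w = _draw_weight(cfg, rng)
    while True:
        v = rng.uniform(0.0, 1.0, size=k)
        v = v - v.mean()
        if np.max(np.abs(v)) < 1e-12:
            continue
        v = v * (abs(w) / v.max())
        if w < 0:
            v = -v
        for _ in range(100):
            if not _is_monotone(v):
                return v
            v = rng.permutation(v)


def _dd_matrix(cfg: SimConfig, rng: np.random.Generator, k: int) -> np.ndarray:
    """k rows, each a permutation of one base vector, no monotone row/column."""
    while True:
        base = _cd_vector(cfg, rng, k)
        perms = [p for p in itertools.permutations(range(k))]
        for _ in range(200):
            rows_idx = rng.choice(len(perms), size=k, replace=False)
            mat = np.array([np.asarray(base)[list(perms[i])] for i in rows_idx])
            rows_ok = all(not _is_monotone(mat[r]) for r in range(k))
            cols_ok = all(not _is_monotone(mat[:, c]) for c in range(k))
            if rows_ok and cols_ok:
                return mat


def assign_parameters(
    dag: MixedGraph, cfg: SimConfig, rng: np.random.Generator
) -> ParamDAG:
    pd_ = ParamDAG(dag=dag)
    for name in dag.node_names:
        var = dag.variable(name)
        if var.is_categorical:
            pd_.disc_node[name] = rng.uniform(-0.2, 0.2, size=var.n_categories)
        else:
            pd_.cont_node[name] = float(rng.uniform(cfg.noise_sd_low, cfg.noise_sd_high))
    for a, b in dag.edges():
        parent, child = (a, b) if dag.is_directed_edge(a, b) else (b, a)
        p_cat = dag.variable(parent).is_categorical
        c_cat = dag.variable(child).is_categorical
        if not p_cat and not c_cat:
            pd_.cc_weights[(parent, child)] = _draw_weight(cfg, rng)
        elif p_cat and c_cat:
            pd_.dd_params[(parent, child)] = _dd_matrix(cfg, rng, cfg.n_categories)
        else:
            k = dag.variable(parent if p_cat else child).n_categories
            pd_.cd_params[(parent, child)] = _cd_vector(cfg, rng, k)
    return pd_


def simulate(pdag: ParamDAG, n: int, rng: np.random.Generator) -> MixedDataset:
    """Ancestral sampling of ``n`` rows from the parameterized DAG."""
    dag = pdag.dag
    order = topological_order(dag)
    values: dict[str, np.ndarray] = {}
    for name in order:
        var = dag.variable(name)
        parents = dag.parents(name)
        if var.is_categorical:
            k = var.n_categories
            logits = np.tile(pdag.disc_node[name], (n, 1))
            for p in parents:
                pvar = dag.variable(p)
                if pvar.is_categorical:
                    logits += pdag.dd_params[(p, name)][values[p], :]
                else:
                    logits += np.outer(values[p], pdag.cd_params[(p, name)])
            logits -= logits.max(axis=1, keepdims=True)  # overflow-safe
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.uniform(0.0, 1.0, size=n)
            cdf = np.cumsum(probs, axis=1)
            values[name] = (u[:, None] > cdf).sum(axis=1).astype(np.int64)
        else:
            mean = np.zeros(n)
            for p in parents:
                pvar = dag.variable(p)
                if pvar.is_categorical:
                    mean += pdag.cd_params[(p, name)][values[p]]
                else:
                    mean += pdag.cc_weights[(p, name)] * values[p]
            values[name] = mean + rng.normal(0.0, pdag.cont_node[name], size=n)
    variables = dag.variables
    frame = pd.DataFrame({v.name: values[v.name] for v in variables})
    return MixedDataset(variables, frame)


def select_latents(
    dag: MixedGraph, k: int, rng: np.random.Generator
) -> set[str]:
    """Pick k latent nodes, each with >= 2 children that stay observed."""
    latents: set[str] = set()
    for _ in range(k):
        eligible = []
        for name in dag.node_names:
            if name in latents:
                continue
            observed_children = [c for c in dag.children(name) if c not in latents]
            if len(observed_children) >= 2:
                eligible.append(name)
        # picking a node may invalidate earlier picks whose children it claims;
        # re-check and bail out to the caller if the pool dries up
        eligible = [
            e
            for e in eligible
            if all(
                len([c for c in dag.children(l) if c not in latents | {e}]) >= 2
                for l in latents
            )
        ]
        if not eligible:
            raise ValueError(
                f"only {len(latents)} nodes with >= 2 observed children; "
                "resample the DAG"
            )
        latents.add(str(rng.choice(sorted(eligible))))
    return latents


def true_pag(
    dag: MixedGraph, latents: set[str], pdsep_depth: int = -1
) -> MixedGraph:
    """Oracle-FCI output over the observed nodes: the best achievable PAG.

    Unlimited conditioning-set depth by default; the Possible-D-Sep subset
    search is exhaustive and exponential in the Possible-D-Sep set size, so a
    ``pdsep_depth`` cap is offered for graphs beyond ~15 nodes.
    """
    observed = [v for v in dag.variables if v.name not in latents]
    test = OracleCITest(dag)
    cfg = fci_engine.SearchConfig(
        mode=fci_engine.Mode.FCI, depth=-1, pdsep_depth=pdsep_depth
    )
    return fci_engine.run(observed, cfg, test)


@dataclass
class SimulatedInstance:
    """One complete simulation draw: graph, parameters, data, truth."""

    dag: MixedGraph
    params: ParamDAG
    latents: set[str]
    data: MixedDataset  # observed columns only
    truth: MixedGraph  # oracle PAG over observed nodes


def generate(
    cfg: SimConfig, max_tries: int = 50, truth_pdsep_depth: int = -1
) -> SimulatedInstance:
    """Draw a DAG (resampling until enough latent candidates), parameterize,
    sample data and build the ground-truth PAG."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max_tries):
        dag = random_dag(cfg, rng)
        try:
            latents = select_latents(dag, cfg.n_latents, rng)
        except ValueError:
            continue
        params = assign_parameters(dag, cfg, rng)
        full = simulate(params, cfg.n_samples, rng)
        data = full.drop(latents)
        truth = true_pag(dag, latents, pdsep_depth=truth_pdsep_depth)
        return SimulatedInstance(dag, params, latents, data, truth)
    raise RuntimeError("could not draw a DAG with enough latent candidates")
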