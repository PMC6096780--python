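"""Mixed graphical model learned by penalized pseudolikelihood minimization.

The pairwise model over p continuous variables x and q categorical variables y
has continuous-continuous interactions beta_st, continuous node potentials
alpha_s, continuous-discrete interaction vectors rho_sj (one entry per
category of y_j), discrete-discrete interaction matrices phi_rj and discrete
node potentials.  Its conditional distributions are Gaussian linear
regressions (unit conditional variance on standardized data) and multiclass
logistic regressions, which makes the negative log pseudolikelihood a smooth
convex function; sparsity comes from an l1 penalty on beta, a group-l2
penalty on each rho vector and a Frobenius penalty on each phi block, fitted
by proximal gradient descent with backtracking line search.

Termination follows an edge-stability rule: stop once the implied edge set is
identical over a window of consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import Endpoint, MixedDataset, MixedGraph, Variable


@dataclass(frozen=True)
class MGMConfig:
    lambda_cc: float = 0.15
    lambda_cd: float = 0.15
    lambda_dd: float = 0.15
    max_iter: int = 1000
    edge_stability_window: int = 3
    step_init: float = 1.0
    step_shrink: float = 0.5
    step_grow: float = 1.05
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if min(self.lambda_cc, self.lambda_cd, self.lambda_dd) < 0:
            raise ValueError("penalties must be nonnegative")
        if self.edge_stability_window < 1:
            raise ValueError("edge_stability_window must be >= 1")

    @classmethod
    def with_lambda(cls, lam: float, **kwargs) -> "MGMConfig":
        return cls(lambda_cc=lam, lambda_cd=lam, lambda_dd=lam, **kwargs)


class _Blocks:
    """Column layout of the stacked indicator matrix for the discrete part."""

    def __init__(self, disc_vars: list[Variable]) -> None:
        self.vars = disc_vars
        self.sizes = [v.n_categories for v in disc_vars]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)]).astype(int)
        self.total = int(self.offsets[-1])

    def sl(self, j: int) -> slice:
        return slice(self.offsets[j], self.offsets[j + 1])


@dataclass
class MGMParams:
    """Full parameter set of the pairwise mixed model.

    Matrices are stored densely: ``rho`` is (K, p) with rows grouped per
    discrete variable (K = total category count) and ``phi`` is (K, K) with
    symmetric off-diagonal blocks phi_rj = phi_jr^T and zero diagonal blocks;
    discrete node potentials live in ``psi``.
    """

    cont_names: list[str]
    disc_names: list[str]
    blocks: _Blocks
    beta: np.ndarray  # (p, p) symmetric, zero diagonal
    alphaC: np.ndarray  # (p,)
    rho: np.ndarray  # (K, p)
    phi: np.ndarray  # (K, K)
    psi: np.ndarray  # (K,)
    noise: np.ndarray = field(default=None)  # per-continuous conditional variances

    def __post_init__(self) -> None:
        if self.noise is None:
            self.noise = np.ones(len(self.cont_names))

    @classmethod
    def zeros(cls, cont: list[Variable], disc: list[Variable]) -> "MGMParams":
        blocks = _Blocks(disc)
        p, K = len(cont), blocks.total
        return cls(
            [v.name for v in cont],
            [v.name for v in disc],
            blocks,
            beta=np.zeros((p, p)),
            alphaC=np.zeros(p),
            rho=np.zeros((K, p)),
            phi=np.zeros((K, K)),
            psi=np.zeros(K),
        )

    # --- block accessors -------------------------------------------------
    def rho_block(self, s: int, j: int) -> np.ndarray:
        """Interaction vector between continuous s and discrete j (length k_j)."""
        return self.rho[self.blocks.sl(j), s]

    def phi_block(self, r: int, j: int) -> np.ndarray:
        """Interaction matrix between discrete r and j (k_r x k_j)."""
        return self.phi[self.blocks.sl(r), self.blocks.sl(j)]

    def copy_like(self, beta, alphaC, rho, phi, psi) -> "MGMParams":
        return MGMParams(
            self.cont_names,
            self.disc_names,
            self.blocks,
            beta,
            alphaC,
            rho,
            phi,
            psi,
            self.noise.copy(),
        )


class _Problem:
    """Preprocessed design: standardized continuous matrix + indicator matrix."""

    def __init__(self, data: MixedDataset) -> None:
        self.cont = [v for v in data.variables if not v.is_categorical]
        self.disc = [v for v in data.variables if v.is_categorical]
        self.blocks = _Blocks(self.disc)
        n = data.n
        if n < 2:
            raise ValueError("need n >= 2 samples")
        X = np.column_stack(
            [data.column(v.name).astype(float) for v in self.cont]
        ) if self.cont else np.empty((n, 0))
        self.x_mean = X.mean(axis=0) if X.size else np.zeros(0)
        sd = X.std(axis=0, ddof=0) if X.size else np.zeros(0)
        sd = np.where(sd > 0, sd, 1.0)
        self.x_sd = sd
        self.X = (X - self.x_mean) / sd
        D = np.zeros((n, self.blocks.total))
        for j, v in enumerate(self.disc):
            codes = data.column(v.name)
            D[np.arange(n), self.blocks.offsets[j] + codes] = 1.0
        self.D = D
        self.n = n

    def smooth_value_grad(self, th: MGMParams):
        """Mean negative log pseudolikelihood and its gradient.

        Continuous conditional variances (``th.noise``) are treated as fixed
        here; :func:`fit` profiles them out between proximal steps.
        """
        X, D, n = self.X, self.D, self.n
        p = X.shape[1]
        tau = th.noise
        # continuous conditionals: x_s ~ N(alpha_s + X beta_{.s} + D rho_{.s}, tau_s)
        pred = th.alphaC[None, :] + X @ th.beta + D @ th.rho
        res = pred - X
        val_c = 0.5 * float(((res * res) / tau[None, :]).sum()) / n
        val_c += 0.5 * float(np.log(2 * np.pi * tau).sum()) if p else 0.0
        res = res / tau[None, :]  # reweight once; reused by every gradient below
        # discrete conditionals: multiclass logits per block
        logits = th.psi[None, :] + X @ th.rho.T + D @ th.phi
        val_d = 0.0
        P = np.zeros_like(logits)
        for j in range(len(self.disc)):
            sl = self.blocks.sl(j)
            block = logits[:, sl]
            m = block.max(axis=1, keepdims=True)
            e = np.exp(block - m)
            z = e.sum(axis=1, keepdims=True)
            P[:, sl] = e / z
            obs = D[:, sl]
            val_d += float(((np.log(z) + m) - (block * obs).sum(axis=1, keepdims=True)).sum()) / n
        E = P - D
        g_alpha = res.sum(axis=0) / n
        G = X.T @ res / n
        g_beta = G + G.T
        np.fill_diagonal(g_beta, 0.0)
        g_rho = (D.T @ res + E.T @ X) / n
        g_psi = E.sum(axis=0) / n
        H = D.T @ E / n
        g_phi = H + H.T
        for j in range(len(self.disc)):
            sl = self.blocks.sl(j)
            g_phi[sl, sl] = 0.0
        nll = val_c + val_d
        return nll, (g_beta, g_alpha, g_rho, g_phi, g_psi)

    def profiled_noise(self, th: MGMParams, floor: float = 1e-3) -> np.ndarray:
        """Per-variable residual variances minimizing the Gaussian terms."""
        pred = th.alphaC[None, :] + self.X @ th.beta + self.D @ th.rho
        res = pred - self.X
        return np.maximum((res * res).mean(axis=0), floor)

    def smooth_value(self, th: MGMParams) -> float:
        return self.smooth_value_grad(th)[0]


def neg_log_pseudolikelihood(params: MGMParams, data: MixedDataset) -> float:
    """Sample-mean negative log pseudolikelihood of ``params`` on ``data``."""
    prob = _Problem(data)
    if [v.name for v in prob.cont] != params.cont_names or [
        v.name for v in prob.disc
    ] != params.disc_names:
        raise ValueError("params not dimensioned to dataset")
    return prob.smooth_value(params)


def _penalty(params: MGMParams, cfg: MGMConfig) -> float:
    blocks = params.blocks
    p = len(params.cont_names)
    q = len(params.disc_names)
    pen = cfg.lambda_cc * float(np.abs(np.triu(params.beta, 1)).sum())
    for s in range(p):
        for j in range(q):
            pen += cfg.lambda_cd * float(np.linalg.norm(params.rho_block(s, j)))
    for j in range(q):
        for r in range(j):
            pen += cfg.lambda_dd * float(np.linalg.norm(params.phi_block(r, j)))
    return pen


def objective(params: MGMParams, data: MixedDataset, cfg: MGMConfig) -> float:
    """Penalized negative log pseudolikelihood."""
    return neg_log_pseudolikelihood(params, data) + _penalty(params, cfg)


def _prox(
    th: MGMParams, grads, step: float, cfg: MGMConfig
) -> MGMParams:
    """Gradient step followed by the per-block shrinkage operators."""
    g_beta, g_alpha, g_rho, g_phi, g_psi = grads
    blocks = th.blocks
    beta = th.beta - step * g_beta
    mag = np.abs(beta) - step * cfg.lambda_cc
    beta = np.sign(beta) * np.maximum(mag, 0.0)
    beta = 0.5 * (beta + beta.T)
    np.fill_diagonal(beta, 0.0)
    alpha = th.alphaC - step * g_alpha
    rho = th.rho - step * g_rho
    q = len(th.disc_names)
    p = len(th.cont_names)
    for j in range(q):
        sl = blocks.sl(j)
        block = rho[sl, :]
        norms = np.linalg.norm(block, axis=0)
        scale = np.zeros(p)
        nz = norms > 0
        scale[nz] = np.maximum(1.0 - step * cfg.lambda_cd / norms[nz], 0.0)
        rho[sl, :] = block * scale[None, :]
    phi = th.phi - step * g_phi
    for j in range(q):
        for r in range(j):
            sr, sj = blocks.sl(r), blocks.sl(j)
            block = phi[sr, sj]
            norm = np.linalg.norm(block)
            scale = max(1.0 - step * cfg.lambda_dd / norm, 0.0) if norm > 0 else 0.0
            phi[sr, sj] = block * scale
            phi[sj, sr] = (block * scale).T
        phi[blocks.sl(j), blocks.sl(j)] = 0.0
    psi = th.psi - step * g_psi
    return th.copy_like(beta, alpha, rho, phi, psi)


def edge_set(params: MGMParams, tol: float = 0.0) -> frozenset:
    """Undirected edges implied by nonzero interaction blocks."""
    edges = set()
    p, q = len(params.cont_names), len(params.disc_names)
    for s in range(p):
        for t in range(s + 1, p):
            if abs(params.beta[s, t]) > tol:
                edges.add(frozenset((params.cont_names[s], params.cont_names[t])))
    for s in range(p):
        for j in range(q):
            if np.linalg.norm(params.rho_block(s, j)) > tol:
                edges.add(frozenset((params.cont_names[s], params.disc_names[j])))
    for j in range(q):
        for r in range(j):
            if np.linalg.norm(params.phi_block(r, j)) > tol:
                edges.add(frozenset((params.disc_names[r], params.disc_names[j])))
    return frozenset(edges)


def params_to_graph(params: MGMParams, variables: list[Variable]) -> MixedGraph:
    g = MixedGraph(variables)
    for pair in edge_set(params):
        a, b = sorted(pair)
        g.add_edge(a, b, Endpoint.CIRCLE, Endpoint.CIRCLE)
    return g


def fit(data: MixedDataset, cfg: MGMConfig) -> tuple[MGMParams, MixedGraph]:
    """Proximal-gradient fit; returns the parameters and the implied skeleton.

    Continuous columns are standardized internally.  Interaction parameters
    start at zero and node potentials at their marginal fits, making the
    result deterministic.
    """
    prob = _Problem(data)
    th = MGMParams.zeros(prob.cont, prob.disc)
    # marginal node-potential initialization (data standardized => alpha = 0)
    freqs = prob.D.mean(axis=0)
    for j in range(len(prob.disc)):
        sl = prob.blocks.sl(j)
        logf = np.log(np.maximum(freqs[sl], 1e-12))
        th.psi[sl] = logf - logf.mean()

    step = cfg.step_init
    f_val, grads = prob.smooth_value_grad(th)
    history: list[frozenset] = [edge_set(th)]
    for _ in range(cfg.max_iter):
        accepted = None
        for _bt in range(60):
            cand = _prox(th, grads, step, cfg)
            f_new = prob.smooth_value(cand)
            if not np.isfinite(f_new):
                step *= cfg.step_shrink
                continue
            diff = _param_diff(cand, th)
            quad = f_val + _inner(grads, diff) + _sqnorm(diff) / (2 * step)
            if f_new <= quad + 1e-12:
                accepted = (cand, f_new)
                break
            step *= cfg.step_shrink
        if accepted is None:
            raise RuntimeError("proximal step failed: objective not finite")
        new_th, f_new = accepted
        moved = _sqnorm(_param_diff(new_th, th))
        th = new_th
        th.noise = prob.profiled_noise(th)  # exact minimizer given th; descent
        f_val, grads = prob.smooth_value_grad(th)
        history.append(edge_set(th))
        if len(history) > cfg.edge_stability_window:
            recent = history[-(cfg.edge_stability_window + 1):]
            if all(e == recent[0] for e in recent) and moved < 1e-4:
                break
        if moved < cfg.tol:
            break
        step *= cfg.step_grow
    graph = params_to_graph(th, list(data.variables))
    return th, graph


def _param_diff(a: MGMParams, b: MGMParams):
    return (
        a.beta - b.beta,
        a.alphaC - b.alphaC,
        a.rho - b.rho,
        a.phi - b.phi,
        a.psi - b.psi,
    )


def _inner(g, d) -> float:
    return float(sum((gi * di).sum() for gi, di in zip(g, d)))


def _sqnorm(d) -> float:
    return float(sum((di * di).sum() for di in d))
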