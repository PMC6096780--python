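"""Conditional-independence tests for mixed data, plus a d-separation oracle.

The data-driven test dispatches on variable types: two continuous variables
use a partial-correlation t test from a linear regression; any pair involving
a categorical variable uses a likelihood-ratio test between nested multinomial
logistic regressions with the categorical variable as the target.  Categorical
predictors enter regressions as binary indicator columns with one reference
category dropped to keep designs full rank.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .graph_core import DagIndex, MixedDataset, MixedGraph, Variable


@dataclass(frozen=True)
class CITestConfig:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class CITestResult:
    pvalue: float
    independent: bool
    dof: int = 0
    degenerate: bool = False


def expand_indicators(
    data: MixedDataset, variables: Iterable[str]
) -> tuple[np.ndarray, list[tuple[str, str | None]], set[str]]:
    """One-hot expansion of the requested columns.

    Each categorical variable with k categories yields k 0/1 columns (one per
    category); continuous variables pass through unchanged.  Returns the design
    matrix, a per-column mapping ``(source variable, category label or None)``,
    and the set of variables that are degenerate (single observed category).
    """
    cols: list[np.ndarray] = []
    mapping: list[tuple[str, str | None]] = []
    degenerate: set[str] = set()
    for name in variables:
        var = data.variable(name)
        values = data.column(name)
        if var.is_categorical:
            if len(np.unique(values)) < 2:
                degenerate.add(name)
            for idx, label in enumerate(var.categories):
                cols.append((values == idx).astype(np.float64))
                mapping.append((name, label))
        else:
            cols.append(values.astype(np.float64))
            mapping.append((name, None))
    if cols:
        design = np.column_stack(cols)
    else:
        design = np.empty((data.n, 0))
    return design, mapping, degenerate


def _predictor_block(data: MixedDataset, names: Sequence[str]) -> tuple[np.ndarray, bool]:
    """Design columns for predictors: reference category dropped per categorical.

    Returns the block and a degeneracy flag (any single-category column).
    """
    cols: list[np.ndarray] = []
    degenerate = False
    for name in names:
        var = data.variable(name)
        values = data.column(name)
        if var.is_categorical:
            if len(np.unique(values)) < 2:
                degenerate = True
            for idx in range(1, var.n_categories):
                cols.append((values == idx).astype(np.float64))
        else:
            cols.append(values.astype(np.float64))
    if cols:
        return np.column_stack(cols), degenerate
    return np.empty((data.n, 0)), degenerate


def _dependent(dof: int = 0, degenerate: bool = True) -> CITestResult:
    return CITestResult(pvalue=0.0, independent=False, dof=dof, degenerate=degenerate)


# ---------------------------------------------------------------------------
# continuous branch
# ---------------------------------------------------------------------------


def _ols_rss(x: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares of x on design; returns (coefs, RSS, rank)."""
    coefs, _, rank, _ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coefs
    return coefs, float(resid @ resid), rank


def test_continuous(
    data: MixedDataset,
    x: str,
    y: str,
    s: Iterable[str],
    cfg: CITestConfig,
) -> CITestResult:
    """t test (continuous y) or F test (categorical y block) on y in x ~ y + s."""
    s = sorted(s)
    xv = data.column(x).astype(np.float64)
    n = data.n
    s_block, s_degen = _predictor_block(data, s)
    y_block, y_degen = _predictor_block(data, [y])
    q = y_block.shape[1]
    if s_degen or y_degen:
        return _dependent(dof=q)
    intercept = np.ones((n, 1))
    full = np.column_stack([intercept, s_block, y_block])
    p_full = full.shape[1]
    if n <= p_full:
        return _dependent(dof=q)
    if not data.is_categorical(y):
        # t test on the single y coefficient
        xtx = full.T @ full
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            return _dependent(dof=1)
        coefs = xtx_inv @ (full.T @ xv)
        resid = xv - full @ coefs
        df = n - p_full
        sigma2 = float(resid @ resid) / df
        var_b = sigma2 * xtx_inv[-1, -1]
        if var_b <= 0 or not np.isfinite(var_b):
            return _dependent(dof=1)
        tstat = coefs[-1] / np.sqrt(var_b)
        pvalue = float(2.0 * stats.t.sf(abs(tstat), df))
        return CITestResult(pvalue, pvalue > cfg.alpha, dof=1)
    # categorical y: joint F test of the indicator block
    null = np.column_stack([intercept, s_block])
    _, rss_full, rank_full = _ols_rss(xv, full)
    _, rss_null, _ = _ols_rss(xv, null)
    if rank_full < p_full:
        return _dependent(dof=q)
    df2 = n - p_full
    num = max(rss_null - rss_full, 0.0) / q
    den = rss_full / df2
    if den <= 0:
        return _dependent(dof=q)
    pvalue = float(stats.f.sf(num / den, q, df2))
    return CITestResult(pvalue, pvalue > cfg.alpha, dof=q)


# ---------------------------------------------------------------------------
# categorical branch: multinomial logistic LRT
# ---------------------------------------------------------------------------


def _multinomial_loglik(
    design: np.ndarray,
    codes: np.ndarray,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[float, bool]:
    """Fit a multinomial logit of codes (values 0..k-1) on design by Newton steps.

    Category 0 is the reference.  Returns (log-likelihood, ok); ``ok`` is False
    on numerical failure (the fit hitting the separation boundary still counts
    as ok — its LRT statistic is what matters).
    """
    n, d = design.shape
    m = k - 1
    w = np.zeros((d, m))
    onehot = np.zeros((n, m))
    for c in range(1, k):
        onehot[:, c - 1] = codes == c
    ll_prev = -np.inf
    ok = True
    ridge = 1e-10
    for _ in range(max_iter):
        eta = design @ w
        eta = np.clip(eta, -500, 500)
        denom = 1.0 + np.exp(eta).sum(axis=1)
        logden = np.log(denom)
        ll = float((eta * onehot).sum() - logden.sum())
        if not np.isfinite(ll):
            return 0.0, False
        if ll - ll_prev < tol and ll >= ll_prev:
            ll_prev = ll
            break
        probs = np.exp(eta) / denom[:, None]
        grad = design.T @ (onehot - probs)  # d x m
        # Hessian blocks H[(a,c1),(b,c2)] = -sum_i x_ia x_ib (delta p - p p)
        hess = np.empty((d * m, d * m))
        for c1 in range(m):
            for c2 in range(c1, m):
                wgt = probs[:, c1] * ((c1 == c2) - probs[:, c2])
                block = design.T @ (design * wgt[:, None])
                hess[c1 * d : (c1 + 1) * d, c2 * d : (c2 + 1) * d] = block
                if c1 != c2:
                    hess[c2 * d : (c2 + 1) * d, c1 * d : (c1 + 1) * d] = block
        hess[np.diag_indices_from(hess)] += ridge
        try:
            step = np.linalg.solve(hess, grad.T.ravel())
        except np.linalg.LinAlgError:
            return ll, False
        step = step.reshape(m, d).T
        # halve the step until the likelihood does not decrease
        scale = 1.0
        for _half in range(30):
            w_new = w + scale * step
            eta_new = np.clip(design @ w_new, -500, 500)
            ll_new = float(
                (eta_new * onehot).sum()
                - np.log1p(np.exp(eta_new).sum(axis=1)).sum()
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            ok = False
            break
        w = w_new
        if abs(ll_new - ll) < tol:
            ll_prev = ll_new
            break
        ll_prev = ll_new
    eta = np.clip(design @ w, -500, 500)
    ll_final = float((eta * onehot).sum() - np.log1p(np.exp(eta).sum(axis=1)).sum())
    return ll_final, ok and np.isfinite(ll_final)


def test_categorical(
    data: MixedDataset,
    x: str,
    y: str,
    s: Iterable[str],
    cfg: CITestConfig,
) -> CITestResult:
    """LRT between multinomial logits of x on s+y (full) versus s alone (null)."""
    if not data.is_categorical(x):
        raise ValueError("test_categorical requires a categorical target")
    s = sorted(s)
    codes = data.column(x).astype(np.int64)
    k = data.variable(x).n_categories
    if len(np.unique(codes)) < 2:
        return _dependent()
    s_block, s_degen = _predictor_block(data, s)
    y_block, y_degen = _predictor_block(data, [y])
    q = y_block.shape[1]
    dof = (k - 1) * q
    if s_degen or y_degen:
        return _dependent(dof=dof)
    n = data.n
    intercept = np.ones((n, 1))
    null_design = np.column_stack([intercept, s_block])
    full_design = np.column_stack([intercept, s_block, y_block])
    if n <= full_design.shape[1] * (k - 1):
        return _dependent(dof=dof)
    if np.linalg.matrix_rank(full_design) < full_design.shape[1]:
        return _dependent(dof=dof)
    ll_null, ok_null = _multinomial_loglik(null_design, codes, k)
    ll_full, ok_full = _multinomial_loglik(full_design, codes, k)
    if not (ok_null and ok_full):
        return _dependent(dof=dof)
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    pvalue = float(stats.chi2.sf(stat, dof))
    return CITestResult(pvalue, pvalue > cfg.alpha, dof=dof)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def _categorical_target(data: MixedDataset, x: str, y: str) -> tuple[str, str]:
    """Choose the regression target for a pair with >= 1 categorical variable."""
    x_cat, y_cat = data.is_categorical(x), data.is_categorical(y)
    if x_cat and y_cat:
        kx = data.variable(x).n_categories
        ky = data.variable(y).n_categories
        if (kx, x) <= (ky, y):  # fewer categories, ties by name order
            return x, y
        return y, x
    return (x, y) if x_cat else (y, x)


def ci_test(
    data: MixedDataset,
    x: str,
    y: str,
    s: Iterable[str],
    cfg: CITestConfig,
) -> CITestResult:
    """Type-dispatched mixed CI test of x against y given s."""
    if x == y or x in s or y in s:
        raise ValueError("require x != y and x, y not in s")
    if not (data.is_categorical(x) or data.is_categorical(y)):
        # the partial-correlation t test is symmetric in (x, y) analytically;
        # fix the regression target by name order so it is symmetric bitwise
        x, y = sorted((x, y))
        return test_continuous(data, x, y, s, cfg)
    target, other = _categorical_target(data, x, y)
    return test_categorical(data, target, other, s, cfg)


class _LRUCache(OrderedDict):
    def __init__(self, maxsize: int) -> None:
        super().__init__()
        self.maxsize = maxsize

    def get_or(self, key, default=None):
        if key in self:
            self.move_to_end(key)
            return self[key]
        return default

    def put(self, key, value) -> None:
        self[key] = value
        self.move_to_end(key)
        if len(self) > self.maxsize:
            self.popitem(last=False)


class RegressionCITest:
    """Callable CI tester over a dataset with an LRU result cache and counters.

    ``n_calls`` counts every independence query (the runtime-relevant figure);
    ``n_computed`` counts cache misses.
    """

    def __init__(
        self, data: MixedDataset, alpha: float = 0.05, cache_size: int = 200_000
    ) -> None:
        self.data = data
        self.cfg = CITestConfig(alpha)
        self.variables = list(data.variables)
        self.n_calls = 0
        self.n_computed = 0
        self._cache = _LRUCache(cache_size)

    @property
    def alpha(self) -> float:
        return self.cfg.alpha

    def __call__(self, x: str, y: str, s: Iterable[str]) -> CITestResult:
        self.n_calls += 1
        key = (frozenset((x, y)), frozenset(s))
        hit = self._cache.get_or(key)
        if hit is not None:
            return hit
        self.n_computed += 1
        result = ci_test(self.data, x, y, s, self.cfg)
        self._cache.put(key, result)
        return result


class OracleCITest:
    """d-separation oracle over a (possibly latent-including) DAG.

    Returns p-value 1 for separated pairs and 0 otherwise, so any alpha in
    (0, 1) yields the same decisions.
    """

    def __init__(self, dag: MixedGraph, alpha: float = 0.05) -> None:
        self._index = DagIndex(dag)
        self.cfg = CITestConfig(alpha)
        self.n_calls = 0
        self.n_computed = 0
        self._cache: dict = {}

    @property
    def alpha(self) -> float:
        return self.cfg.alpha

    def __call__(self, x: str, y: str, s: Iterable[str]) -> CITestResult:
        self.n_calls += 1
        key = (frozenset((x, y)), frozenset(s))
        if key in self._cache:
            return self._cache[key]
        self.n_computed += 1
        indep = self._index.d_separated(x, y, frozenset(s))
        result = CITestResult(1.0 if indep else 0.0, indep, dof=0)
        self._cache[key] = result
        return result


def oracle_ci_test(
    g: MixedGraph, x: str, y: str, s: Iterable[str] = ()
) -> CITestResult:
    """One-shot oracle query; see :class:`OracleCITest` for repeated use."""
    return OracleCITest(g)(x, y, s)
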