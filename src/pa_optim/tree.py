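"""Conditional inference tree (CIT) over predicted optimal PA patterns.

Characterizes which covariates drive heterogeneity in the individually
optimal pattern: recursive binary partitioning in which each split is
chosen by a permutation-framework test of independence between a covariate
and the multinomial pattern outcome, with Bonferroni adjustment across
covariates and early stopping once no adjusted p-value clears alpha.

The node-level test uses the standardized linear statistic

    T = sum_i g(x_i) h(y_i)^T,

with g the identity for ordered covariates (indicator coding for
categorical ones) and h the outcome class indicators.  T is centred and
scaled by its conditional expectation and covariance under permutations of
x, and the quadratic form against the Moore-Penrose inverse of that
covariance is referred to its asymptotic chi-squared distribution (a
Monte-Carlo permutation p-value is available for small nodes).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accelerometry import PATTERN_ORDER

PATTERNS = [p.value for p in PATTERN_ORDER]


# ---------------------------------------------------------------------------
# Association test
# ---------------------------------------------------------------------------


def _one_hot(y: np.ndarray) -> tuple[np.ndarray, list]:
    classes = sorted(pd.unique(y), key=lambda v: str(v))
    h = np.column_stack([(y == c).astype(float) for c in classes])
    return h, classes


def _linear_statistic(g: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(vec(T - mu), Sigma, T) under the permutation null with unit weights."""
    n = len(g)
    if g.ndim == 1:
        g = g[:, None]
    T = g.T @ h  # p x q
    gsum = g.sum(axis=0)  # (p,)
    hbar = h.mean(axis=0)  # (q,)
    hc = h - hbar
    V = (hc.T @ hc) / n  # q x q conditional covariance of h
    mu = np.outer(gsum, hbar)
    A = g.T @ g  # p x p
    G = np.outer(gsum, gsum)
    # Cov(vec(T)) with Fortran (column-major) vec: classes index the blocks
    sigma = (n / (n - 1.0)) * np.kron(V, A) - (1.0 / (n - 1.0)) * np.kron(V, G)
    d = (T - mu).ravel(order="F")
    return d, sigma, T


def _chi2_logsf(stat: float, df: int) -> float:
    """log survival function of chi-squared; stays informative where the
    p-value itself underflows, so far-significant tests remain comparable."""
    val = float(stats.chi2.logsf(stat, df))
    if np.isfinite(val):
        return val
    from scipy.special import gammaln

    # leading term of the upper-tail expansion for very large statistics
    x = stat / 2.0
    return float(-x + (df / 2.0 - 1.0) * np.log(x) - gammaln(df / 2.0))


def _quad_form(d: np.ndarray, sigma: np.ndarray) -> tuple[float, int]:
    """Moore-Penrose quadratic form and its rank (chi-squared df)."""
    sinv = np.linalg.pinv(sigma, rcond=1e-10, hermitian=True)
    stat = float(d @ sinv @ d)
    rank = int(np.linalg.matrix_rank(sigma, tol=1e-10, hermitian=True))
    return stat, rank


def cit_association_test(
    y: np.ndarray,
    x: np.ndarray,
    kind: str = "ordered",
    n_permutations: int = 0,
    seed: int = 0,
) -> float:
    """Permutation-framework independence test of covariate x vs classes y.

    Returns the asymptotic chi-squared p-value of the standardized
    quadratic statistic, or a Monte-Carlo permutation p-value when
    ``n_permutations`` > 0.
    """
    y = np.asarray(y)
    x = np.asarray(x)
    if len(pd.unique(y)) < 2:
        raise ValueError("need >= 2 outcome classes in the node")
    if len(pd.unique(x)) < 2:
        raise ValueError("constant covariate in node")
    h, _ = _one_hot(y)
    if kind == "ordered":
        g = np.asarray(x, dtype=float)[:, None]
    elif kind == "categorical":
        g, _ = _one_hot(x)
    else:
        raise ValueError("kind must be 'ordered' or 'categorical'")
    d, sigma, _ = _linear_statistic(g, h)
    stat, df = _quad_form(d, sigma)
    if n_permutations <= 0:
        return float(np.exp(_chi2_logsf(stat, df)))
    rng = np.random.default_rng(seed)
    sinv = np.linalg.pinv(sigma, rcond=1e-10, hermitian=True)
    count = 0
    for _ in range(n_permutations):
        gp = g[rng.permutation(len(g))]
        dp = (gp.T @ h - (gp.sum(axis=0)[:, None] * h.mean(axis=0)[None, :])).ravel(order="F")
        if dp @ sinv @ dp >= stat - 1e-12:
            count += 1
    return (1.0 + count) / (n_permutations + 1.0)


# ---------------------------------------------------------------------------
# Cutpoint search
# ---------------------------------------------------------------------------


def _best_cutpoint(
    x: np.ndarray, h: np.ndarray, min_child: int
) -> tuple[float | None, float]:
    """Threshold maximizing the standardized two-sample statistic.

    For a binary split indicator s = [x <= c] the quadratic statistic
    reduces to (n-1)/(n_l n_r) * d_c' V^+ d_c with d_c the centred class
    totals of the left child; all thresholds are scored in one vectorised
    sweep over the sorted sample.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    hs = h[order]
    hbar = h.mean(axis=0)
    V = ((h - hbar).T @ (h - hbar)) / n
    Vinv = np.linalg.pinv(V, rcond=1e-10, hermitian=True)
    cum = np.cumsum(hs, axis=0)  # prefix class totals
    n_l = np.arange(1, n + 1, dtype=float)
    d = cum - n_l[:, None] * hbar[None, :]
    quad = np.einsum("ij,jk,ik->i", d, Vinv, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (n - 1.0) * quad / (n_l * (n - n_l))
    # valid thresholds: where x strictly increases, respecting child sizes
    boundary = np.append(xs[:-1] < xs[1:], False)
    valid = boundary & (n_l >= min_child) & ((n - n_l) >= min_child)
    if not valid.any():
        return None, 0.0
    idx = int(np.nanargmax(np.where(valid, stat, -np.inf)))
    return float(xs[idx]), float(stat[idx])


# ---------------------------------------------------------------------------
# Tree growth
# ---------------------------------------------------------------------------


@dataclass
class CITNode:
    node_id: int
    depth: int
    n: int
    distribution: dict[str, float]
    split_var: str | None = None
    split_point: float | None = None
    p_value: float | None = None  # Bonferroni-adjusted p of the selected test
    children: list["CITNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def majority(self) -> str:
        return max(self.distribution, key=self.distribution.get)

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "n": self.n,
            "distribution": self.distribution,
            "split_var": self.split_var,
            "split_point": self.split_point,
            "p_value": self.p_value,
        }
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class CITree:
    root: CITNode
    predictors: list[str]
    alpha: float
    min_node: int
    max_depth: int
    outcome_classes: list[str]

    @property
    def depth(self) -> int:
        def _d(node):
            return node.depth if node.is_leaf else max(_d(c) for c in node.children)

        return _d(self.root)

    @property
    def n_leaves(self) -> int:
        def _l(node):
            return 1 if node.is_leaf else sum(_l(c) for c in node.children)

        return _l(self.root)

    def to_json(self, path=None) -> str:
        payload = {
            "predictors": self.predictors,
            "alpha": self.alpha,
            "min_node": self.min_node,
            "max_depth": self.max_depth,
            "outcome_classes": self.outcome_classes,
            "root": self.root.to_dict(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def render_text(self) -> str:
        lines: list[str] = []

        def walk(node: CITNode, prefix: str) -> None:
            if node.is_leaf:
                dist = ", ".join(f"{k}={v:.2f}" for k, v in node.distribution.items() if v > 0)
                lines.append(f"{prefix}[{node.node_id}] leaf n={node.n} ({dist})")
            else:
                lines.append(
                    f"{prefix}[{node.node_id}] {node.split_var} <= {node.split_point:g} "
                    f"(adj p={node.p_value:.3g}, n={node.n})"
                )
                walk(node.children[0], prefix + "  ")
                lines.append(f"{prefix}[{node.node_id}] {node.split_var} > {node.split_point:g}")
                walk(node.children[1], prefix + "  ")

        walk(self.root, "")
        return "\n".join(lines)


def _distribution(y: np.ndarray, classes: list[str]) -> dict[str, float]:
    n = len(y)
    return {c: float((y == c).sum()) / n for c in classes}


def grow_cit(
    data: pd.DataFrame,
    outcome: str = "optimal",
    predictors: list[str] | None = None,
    alpha: float = 0.05,
    min_node: int = 200,
    min_child: int = 50,
    max_depth: int = 5,
) -> CITree:
    """Grow a conditional inference tree.

    At each node every non-constant predictor is tested against the
    outcome, p-values are Bonferroni-adjusted across the predictors tested,
    and growth stops when the smallest adjusted p exceeds ``alpha`` or the
    node size/depth limits bind; otherwise the node splits on the most
    significant predictor at the cutpoint maximizing the two-sample
    statistic.  Ties in adjusted p resolve by predictor order.
    """
    if predictors is None:
        predictors = [c for c in data.columns if c != outcome]
    if data[predictors + [outcome]].isna().any().any():
        raise ValueError("outcome and predictors must be complete (no missing values)")
    y_all = data[outcome].to_numpy(dtype=object)
    classes = [c for c in PATTERNS if c in set(y_all)] or sorted(set(y_all), key=str)
    counter = itertools.count()

    def build(idx: np.ndarray, depth: int) -> CITNode:
        y = y_all[idx]
        node = CITNode(
            node_id=next(counter),
            depth=depth,
            n=len(idx),
            distribution=_distribution(y, classes),
        )
        if len(idx) < min_node or depth >= max_depth or len(pd.unique(y)) < 2:
            return node
        # compare tests on the log scale so far-significant predictors do
        # not collapse into a p == 0 tie
        h_node, _ = _one_hot(y)
        m_tested = 0
        best_logp, best_var = np.inf, None
        for var in predictors:
            x = data[var].to_numpy(dtype=float)[idx]
            if len(pd.unique(x)) < 2:
                continue
            m_tested += 1
            d, sigma, _ = _linear_statistic(x[:, None], h_node)
            stat, dof = _quad_form(d, sigma)
            logp = _chi2_logsf(stat, dof)
            if logp < best_logp:
                best_logp, best_var = logp, var
        if best_var is None:
            return node
        logp_adj = min(0.0, best_logp + np.log(m_tested))
        p_adj = float(np.exp(logp_adj))
        if p_adj > alpha:
            return node
        x = data[best_var].to_numpy(dtype=float)[idx]
        h, _ = _one_hot(y)
        cut, _stat = _best_cutpoint(x, h, min_child)
        if cut is None:
            return node
        node.split_var = best_var
        node.split_point = cut
        node.p_value = p_adj
        left = idx[x <= cut]
        right = idx[x > cut]
        node.children = [build(left, depth + 1), build(right, depth + 1)]
        return node

    root = build(np.arange(len(data)), 0)
    return CITree(
        root=root,
        predictors=list(predictors),
        alpha=alpha,
        min_node=min_node,
        max_depth=max_depth,
        outcome_classes=classes,
    )


def cit_predict(tree: CITree, covariates: pd.DataFrame) -> pd.DataFrame:
    """Route each row to its unique leaf; returns distribution + majority."""
    rows = []
    for _, row in covariates.iterrows():
        node = tree.root
        while not node.is_leaf:
            if node.split_var not in row.index or pd.isna(row[node.split_var]):
                raise ValueError(f"missing split covariate {node.split_var!r}")
            node = node.children[0] if row[node.split_var] <= node.split_point else node.children[1]
        rec = {"leaf_id": node.node_id, "majority": node.majority}
        rec.update({f"p_{c}": v for c, v in node.distribution.items()})
        rows.append(rec)
    return pd.DataFrame(rows, index=covariates.index)
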