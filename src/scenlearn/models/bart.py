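"""Bayesian additive regression trees: a minimal sum-of-trees sampler.

The response is modelled as a sum of ``m`` small regression trees plus
Gaussian noise,

    Y = sum_j g(X; T_j, M_j) + eps,    eps ~ N(0, sigma^2),

where ``T_j`` is the j-th tree's structure, ``M_j`` its leaf parameters and
``g`` assigns each row to a leaf. Regularizing priors keep the individual
trees weak: the probability that a node at depth ``d`` splits is
``alpha (1 + d)^-beta``; leaf values are i.i.d. ``N(0, sigma_mu^2)`` with
``sigma_mu = 0.5 / (k sqrt(m))`` on the internally rescaled response; and
``sigma^2`` carries a scaled-inverse-chi-squared prior calibrated so that a
prior quantile ``q`` sits at the sample standard deviation.

Sampling is Bayesian backfitting: each tree in turn sees the partial
residual of the other trees, its structure is updated by a
Metropolis-Hastings GROW/PRUNE step with leaf values integrated out
analytically, new leaf values are then drawn conjugately, and finally
``sigma^2`` is drawn from its conjugate full conditional.

Point predictions are posterior means over the kept draws; per-draw
predictions back the credible bands; variable importance is the inclusion
proportion — the fraction of splitting rules across all kept forests that
use a given predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .base import FittedModel, ModelSpec, register_family


@dataclass
class _Node:
    depth: int
    var: int = -1          # -1 marks a leaf
    cut: float = np.nan
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.var < 0


def _leaves(node: _Node) -> list[_Node]:
    if node.is_leaf:
        return [node]
    return _leaves(node.left) + _leaves(node.right)


def _prunable(node: _Node) -> list[_Node]:
    """Internal nodes whose both children are leaves."""
    if node.is_leaf:
        return []
    out = []
    if node.left.is_leaf and node.right.is_leaf:
        out.append(node)
    return out + _prunable(node.left) + _prunable(node.right)


def _assign(node: _Node, X: np.ndarray, idx: np.ndarray, out: dict) -> None:
    if node.is_leaf:
        out[id(node)] = idx
        return
    mask = X[idx, node.var] <= node.cut
    _assign(node.left, X, idx[mask], out)
    _assign(node.right, X, idx[~mask], out)


def _tree_predict(node: _Node, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if nd.is_leaf:
            out[idx] = nd.value
        else:
            mask = X[idx, nd.var] <= nd.cut
            stack.append((nd.left, idx[mask]))
            stack.append((nd.right, idx[~mask]))
    return out


def _freeze(node: _Node):
    if node.is_leaf:
        return ("L", node.value)
    return ("S", node.var, node.cut, _freeze(node.left), _freeze(node.right))


def _frozen_predict(tree, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(tree, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if nd[0] == "L":
            out[idx] = nd[1]
        else:
            mask = X[idx, nd[1]] <= nd[2]
            stack.append((nd[3], idx[mask]))
            stack.append((nd[4], idx[~mask]))
    return out


def _frozen_split_vars(tree, counts: np.ndarray) -> None:
    if tree[0] == "S":
        counts[tree[1]] += 1
        _frozen_split_vars(tree[3], counts)
        _frozen_split_vars(tree[4], counts)


class _Sampler:
    def __init__(self, X, y, m, alpha, beta, k, nu, q, n_cuts, rng):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        self.m = m
        self.alpha, self.beta = alpha, beta
        self.rng = rng
        self.sigma_mu = 0.5 / (k * math.sqrt(m))
        # candidate cutpoints: interior quantiles per predictor
        self.cuts = []
        for j in range(self.p):
            u = np.unique(np.quantile(X[:, j], np.linspace(0, 1, n_cuts + 2)[1:-1]))
            u = u[(u > X[:, j].min()) & (u < X[:, j].max())]
            self.cuts.append(u)
        # sigma prior calibrated at the sample sd of the rescaled response
        sd = max(float(np.std(y)), 1e-6)
        self.nu = nu
        self.lam = sd**2 * stats.chi2.ppf(1 - q, nu) / nu
        self.sigma2 = sd**2
        self.trees = [_Node(depth=0) for _ in range(m)]
        self.fits = np.zeros((m, self.n))

    # -- integrated leaf likelihood --------------------------------------
    def _leaf_logml(self, resid_sum: float, n_l: int) -> float:
        s2, sm2 = self.sigma2, self.sigma_mu**2
        v = s2 + n_l * sm2
        return 0.5 * math.log(s2 / v) + sm2 * resid_sum**2 / (2 * s2 * v)

    def _p_split(self, depth: int) -> float:
        return self.alpha * (1.0 + depth) ** (-self.beta)

    def _update_tree(self, t: int) -> None:
        resid = self.y - (self.total - self.fits[t])
        tree = self.trees[t]
        leaves = _leaves(tree)
        assign: dict = {}
        _assign(tree, self.X, np.arange(self.n), assign)

        grow = tree.is_leaf or self.rng.random() < 0.5
        if grow:
            self._try_grow(t, tree, resid, leaves, assign)
        else:
            self._try_prune(t, tree, resid, assign)

        # conjugate leaf-value draws given accepted structure
        assign = {}
        _assign(tree, self.X, np.arange(self.n), assign)
        for leaf in _leaves(tree):
            idx = assign[id(leaf)]
            n_l = len(idx)
            s2, sm2 = self.sigma2, self.sigma_mu**2
            post_var = 1.0 / (1.0 / sm2 + n_l / s2)
            post_mean = post_var * resid[idx].sum() / s2 if n_l else 0.0
            leaf.value = post_mean + math.sqrt(post_var) * self.rng.standard_normal()
        new_fit = _tree_predict(tree, self.X)
        self.total += new_fit - self.fits[t]
        self.fits[t] = new_fit

    def _try_grow(self, t, tree, resid, leaves, assign):
        leaf = leaves[self.rng.integers(len(leaves))]
        idx = assign[id(leaf)]
        if len(idx) < 2:
            return
        var = int(self.rng.integers(self.p))
        xv = self.X[idx, var]
        lo, hi = xv.min(), xv.max()
        avail = self.cuts[var][(self.cuts[var] >= lo) & (self.cuts[var] < hi)]
        if len(avail) == 0:
            return
        cut = float(avail[self.rng.integers(len(avail))])
        mask = xv <= cut
        nl, nr = int(mask.sum()), int((~mask).sum())
        if nl == 0 or nr == 0:
            return
        sl, sr = resid[idx[mask]].sum(), resid[idx[~mask]].sum()
        s_all = resid[idx].sum()

        d = leaf.depth
        log_ml = (
            self._leaf_logml(sl, nl)
            + self._leaf_logml(sr, nr)
            - self._leaf_logml(s_all, len(idx))
        )
        ps, ps1 = self._p_split(d), self._p_split(d + 1)
        log_prior = math.log(ps) + 2 * math.log(1 - ps1) - math.log(1 - ps)
        # prunable count of the proposed tree: the grown leaf becomes a
        # prunable internal node; its parent (if prunable) stops being one
        n_prunable_after = self._prunable_after_grow(tree, leaf)
        log_prop = math.log(len(leaves)) - math.log(max(n_prunable_after, 1))
        if math.log(self.rng.random() + 1e-300) < log_ml + log_prior + log_prop:
            leaf.var, leaf.cut = var, cut
            leaf.left = _Node(depth=d + 1)
            leaf.right = _Node(depth=d + 1)

    def _prunable_after_grow(self, tree: _Node, leaf: _Node) -> int:
        # growing `leaf` makes it a prunable internal node; its parent (if it
        # was prunable) stops being prunable
        count = len(_prunable(tree)) + 1
        parent = self._find_parent(tree, leaf)
        if parent is not None and parent.left.is_leaf and parent.right.is_leaf:
            count -= 1
        return count

    @staticmethod
    def _find_parent(node: _Node, target: _Node) -> _Node | None:
        if node.is_leaf:
            return None
        if node.left is target or node.right is target:
            return node
        return _Sampler._find_parent(node.left, target) or _Sampler._find_parent(
            node.right, target
        )

    def _try_prune(self, t, tree, resid, assign):
        prunable = _prunable(tree)
        if not prunable:
            return
        node = prunable[self.rng.integers(len(prunable))]
        il = assign[id(node.left)]
        ir = assign[id(node.right)]
        sl, sr = resid[il].sum(), resid[ir].sum()
        nl, nr = len(il), len(ir)

        d = node.depth
        log_ml = (
            self._leaf_logml(sl + sr, nl + nr)
            - self._leaf_logml(sl, nl)
            - self._leaf_logml(sr, nr)
        )
        ps, ps1 = self._p_split(d), self._p_split(d + 1)
        log_prior = math.log(1 - ps) - math.log(ps) - 2 * math.log(1 - ps1)
        n_leaves_after = len(_leaves(tree)) - 1
        log_prop = math.log(len(prunable)) - math.log(n_leaves_after)
        if math.log(self.rng.random() + 1e-300) < log_ml + log_prior + log_prop:
            node.var = -1
            node.left = node.right = None

    def run(self, n_burn: int, n_keep: int):
        self.total = self.fits.sum(axis=0)
        kept_forests, kept_sigma2 = [], []
        for it in range(n_burn + n_keep):
            for t in range(self.m):
                self._update_tree(t)
            resid = self.y - self.total
            shape = (self.nu + self.n) / 2.0
            scale = (self.nu * self.lam + float(resid @ resid)) / 2.0
            self.sigma2 = scale / self.rng.gamma(shape)
            if it >= n_burn:
                kept_forests.append([_freeze(tr) for tr in self.trees])
                kept_sigma2.append(self.sigma2)
        return kept_forests, np.array(kept_sigma2)


class _BART(FittedModel):
    def __init__(self, spec, columns, forests, sigma2, y_min, y_span, p):
        super().__init__(spec, columns)
        self._forests = forests
        self.sigma2_draws_ = sigma2  # on the rescaled (unit-span) response scale
        self._y_min, self._y_span = y_min, y_span
        self._p = p

    def _draws_raw(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((len(self._forests), len(X)))
        for i, forest in enumerate(self._forests):
            for tree in forest:
                out[i] += _frozen_predict(tree, X)
        return (out + 0.5) * self._y_span + self._y_min

    def _predict(self, X):
        return self._draws_raw(X).mean(axis=0)

    def predict_draws(self, X):
        return self._draws_raw(self._check_columns(X))

    @property
    def sigma_draws(self) -> np.ndarray:
        """Posterior draws of the noise SD on the response scale."""
        return np.sqrt(self.sigma2_draws_) * self._y_span

    def importance(self):
        counts = np.zeros(self._p)
        for forest in self._forests:
            for tree in forest:
                _frozen_split_vars(tree, counts)
        if counts.sum() == 0:
            counts[:] = 1.0
        return dict(zip(self.columns, counts / counts.sum()))


class _ConstantModel(FittedModel):
    def __init__(self, spec, columns, value):
        super().__init__(spec, columns)
        self._value = float(value)

    def _predict(self, X):
        return np.full(len(X), self._value)

    def predict_draws(self, X):
        return np.full((1, len(self._check_columns(X))), self._value)


@register_family("bart")
def _fit_bart(spec: ModelSpec, X, y, names) -> FittedModel:
    p = spec.params
    m = p.get("n_trees", 50)
    n_burn = p.get("n_burn", 200)
    n_keep = p.get("n_draws", 500)
    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:
        # degenerate zero-variance response: the posterior collapses
        return _ConstantModel(spec, names, y_min)
    y_span = y_max - y_min
    ys = (y - y_min) / y_span - 0.5
    rng = np.random.default_rng(spec.seed)
    sampler = _Sampler(
        X,
        ys,
        m=m,
        alpha=p.get("alpha", 0.95),
        beta=p.get("beta", 2.0),
        k=p.get("k", 2.0),
        nu=p.get("nu", 3.0),
        q=p.get("q", 0.9),
        n_cuts=p.get("n_cuts", 50),
        rng=rng,
    )
    forests, sigma2 = sampler.run(n_burn, n_keep)
    return _BART(spec, names, forests, sigma2, y_min, y_span, X.shape[1])
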