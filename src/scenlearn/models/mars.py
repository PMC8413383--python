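"""Multivariate adaptive regression splines (forward/backward hinge search).

A compact implementation of the classic procedure: the forward pass
greedily adds mirrored hinge pairs ``parent * max(0, x - t)`` and
``parent * max(0, t - x)`` (knots drawn from quantiles of each predictor),
up to ``max_terms`` basis functions and a maximum interaction ``degree``;
the backward pass prunes terms one at a time, keeping the submodel with the
best generalized cross-validation score

    GCV(M) = RSS/n / (1 - C(M)/n)^2,   C(M) = k + penalty * h,

where k counts coefficients and h counts hinge knots. ``degree`` in
{1, 2, 3} and ``penalty`` (default 2) are the registered variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import FittedModel, ModelSpec, register_family


@dataclass(frozen=True)
class _Hinge:
    var: int
    knot: float
    sign: int  # +1: max(0, x-t); -1: max(0, t-x)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        d = (X[:, self.var] - self.knot) * self.sign
        return np.maximum(d, 0.0)


@dataclass(frozen=True)
class _Term:
    hinges: tuple  # empty tuple = intercept

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(len(X))
        for h in self.hinges:
            out *= h(X)
        return out

    @property
    def degree(self) -> int:
        return len(self.hinges)

    def vars(self) -> set[int]:
        return {h.var for h in self.hinges}


def _lstsq_rss(B: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _gcv(rss: float, n: int, n_terms: int, n_knots: int, penalty: float) -> float:
    c = n_terms + penalty * n_knots
    denom = (1.0 - c / n) ** 2
    if denom <= 0:
        return np.inf
    return rss / n / denom


class _MARS(FittedModel):
    def __init__(self, spec, columns, terms, coef):
        super().__init__(spec, columns)
        self.terms_ = terms
        self.coef_ = coef

    def _design(self, X):
        return np.column_stack([t.evaluate(X) for t in self.terms_])

    def _predict(self, X):
        return self._design(X) @ self.coef_


@register_family("mars")
def _fit_mars(spec: ModelSpec, X, y, names) -> FittedModel:
    p = spec.params
    max_degree = p.get("degree", 1)
    penalty = p.get("penalty", 2.0)
    n, nvar = X.shape
    max_terms = p.get("max_terms", min(2 * nvar + 1, 21, max(n - 2, 1)))
    n_knot_candidates = p.get("n_knots", 7)

    # candidate knots: interior quantiles per variable
    qs = np.linspace(0.05, 0.95, n_knot_candidates)
    knots = [np.unique(np.quantile(X[:, j], qs)) for j in range(nvar)]

    terms: list[_Term] = [_Term(())]
    B = np.ones((n, 1))
    _, best_rss = _lstsq_rss(B, y)

    # forward pass: add mirrored hinge pairs while RSS improves meaningfully
    sst = float(np.sum((y - y.mean()) ** 2)) or 1.0
    while len(terms) + 2 <= max_terms:
        best = None
        for mi, parent in enumerate(terms):
            if parent.degree >= max_degree:
                continue
            pb = B[:, mi]
            for v in range(nvar):
                if v in parent.vars():
                    continue
                for t in knots[v]:
                    h1 = pb * np.maximum(X[:, v] - t, 0.0)
                    h2 = pb * np.maximum(t - X[:, v], 0.0)
                    cand = np.column_stack([B, h1, h2])
                    _, rss = _lstsq_rss(cand, y)
                    if best is None or rss < best[0]:
                        best = (rss, mi, v, t)
        if best is None:
            break
        rss, mi, v, t = best
        if best_rss - rss < 1e-10 * sst:
            break
        parent = terms[mi]
        for sign in (+1, -1):
            terms.append(_Term(parent.hinges + (_Hinge(v, float(t), sign),)))
        B = np.column_stack([t_.evaluate(X) for t_ in terms])
        best_rss = rss

    # backward pass: prune by GCV
    def knot_count(tt):
        return sum(t.degree for t in tt)

    def fit_terms(tt):
        Bt = np.column_stack([t.evaluate(X) for t in tt])
        coef, rss = _lstsq_rss(Bt, y)
        return coef, rss

    current = list(terms)
    coef, rss = fit_terms(current)
    best_model = (current, coef)
    best_gcv = _gcv(rss, n, len(current), knot_count(current), penalty)
    while len(current) > 1:
        trial_best = None
        for i in range(1, len(current)):  # never drop the intercept
            tt = current[:i] + current[i + 1:]
            c, r = fit_terms(tt)
            g = _gcv(r, n, len(tt), knot_count(tt), penalty)
            if trial_best is None or g < trial_best[0]:
                trial_best = (g, tt, c)
        g, tt, c = trial_best
        current = tt
        if g <= best_gcv + 1e-12:
            best_gcv, best_model = g, (tt, c)

    final_terms, final_coef = best_model
    return _MARS(spec, names, final_terms, final_coef)
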