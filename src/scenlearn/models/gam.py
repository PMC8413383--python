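"""Generalized additive model: per-predictor B-spline basis + ridge penalty.

Each continuous predictor gets a cubic B-spline basis; the smoothing
penalty is a single ridge penalty on the basis coefficients, selected by
efficient leave-one-out cross-validation (the GCV-style criterion RidgeCV
computes in closed form). Predictors with too few distinct values to
support knots enter linearly.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import RidgeCV
from sklearn.preprocessing import SplineTransformer

from .base import FittedModel, ModelSpec, register_family

_ALPHAS = np.logspace(-4, 6, 21)


class _GAM(FittedModel):
    def __init__(self, spec, columns, transformers, ridge):
        super().__init__(spec, columns)
        self._transformers = transformers  # per-column SplineTransformer or None
        self._ridge = ridge

    def _basis(self, X: np.ndarray) -> np.ndarray:
        blocks = []
        for j, tr in enumerate(self._transformers):
            col = X[:, [j]]
            blocks.append(col if tr is None else tr.transform(np.clip(
                col, self._bounds[j][0], self._bounds[j][1])))
        return np.hstack(blocks)

    def _predict(self, X):
        return self._ridge.predict(self._basis(X))


@register_family("gam")
def _fit_gam(spec: ModelSpec, X, y, names) -> FittedModel:
    p = spec.params
    n_knots = p.get("n_knots", 6)
    degree = p.get("degree", 3)
    transformers, blocks, bounds = [], [], []
    for j in range(X.shape[1]):
        col = X[:, [j]]
        bounds.append((col.min(), col.max()))
        if len(np.unique(col)) > n_knots + degree:
            tr = SplineTransformer(
                n_knots=n_knots, degree=degree, knots="quantile", include_bias=False
            ).fit(col)
            transformers.append(tr)
            blocks.append(tr.transform(col))
        else:
            transformers.append(None)
            blocks.append(col)
    B = np.hstack(blocks)
    ridge = RidgeCV(alphas=_ALPHAS).fit(B, y)
    m = _GAM(spec, names, transformers, ridge)
    m._bounds = bounds  # clamp extrapolation to the training range
    return m
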