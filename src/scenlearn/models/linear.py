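"""Parametric members of the library: GLM (Gaussian), ridge and lasso."""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import Lasso, Ridge

from .base import FitError, FittedModel, ModelSpec, register_family


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    """Name columns that add no rank to the design (via QR diagonal)."""
    A = np.column_stack([np.ones(len(X)), X])
    _, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps * 100
    bad = [i - 1 for i in range(1, A.shape[1]) if diag[i] < tol]
    return [names[i] for i in bad]


class _LinearModel(FittedModel):
    def __init__(self, spec, columns, coef, intercept):
        super().__init__(spec, columns)
        self.coef_ = np.asarray(coef, float)
        self.intercept_ = float(intercept)

    def _predict(self, X):
        return X @ self.coef_ + self.intercept_


@register_family("glm")
def _fit_glm(spec: ModelSpec, X, y, names) -> FittedModel:
    bad = _collinear_columns(X, names)
    if bad:
        raise FitError(f"glm: singular design; collinear columns: {bad}")
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return _LinearModel(spec, names, res.params[1:], res.params[0])


@register_family("ridge")
def _fit_ridge(spec: ModelSpec, X, y, names) -> FittedModel:
    alpha = spec.params.get("alpha", 1.0)
    m = Ridge(alpha=alpha).fit(X, y)
    return _LinearModel(spec, names, m.coef_, m.intercept_)


@register_family("lasso")
def _fit_lasso(spec: ModelSpec, X, y, names) -> FittedModel:
    alpha = spec.params.get("alpha", 0.01)
    m = Lasso(alpha=alpha, max_iter=50_000).fit(X, y)
    return _LinearModel(spec, names, m.coef_, m.intercept_)
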