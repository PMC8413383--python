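"""Tree-ensemble members: random forest and gradient boosting."""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .base import FittedModel, ModelSpec, register_family


class _SKEnsemble(FittedModel):
    def __init__(self, spec, columns, est):
        super().__init__(spec, columns)
        self._est = est

    def _predict(self, X):
        return self._est.predict(X)

    def importance(self):
        imp = np.asarray(self._est.feature_importances_, float)
        total = imp.sum()
        if total <= 0:
            imp = np.ones_like(imp)
            total = imp.sum()
        return dict(zip(self.columns, imp / total))


@register_family("random_forest")
def _fit_rf(spec: ModelSpec, X, y, names) -> FittedModel:
    p = spec.params
    est = RandomForestRegressor(
        n_estimators=p.get("n_estimators", 200),
        max_depth=p.get("max_depth"),
        min_samples_leaf=p.get("min_samples_leaf", 2),
        max_features=p.get("max_features", 1.0 / 3),
        bootstrap=p.get("bootstrap", True),
        random_state=spec.seed,
        n_jobs=1,
    ).fit(X, y)
    return _SKEnsemble(spec, names, est)


@register_family("gbm")
def _fit_gbm(spec: ModelSpec, X, y, names) -> FittedModel:
    p = spec.params
    est = GradientBoostingRegressor(
        n_estimators=p.get("n_estimators", 200),
        learning_rate=p.get("learning_rate", 0.05),
        max_depth=p.get("max_depth", 3),
        subsample=p.get("subsample", 0.8),
        random_state=spec.seed,
    ).fit(X, y)
    return _SKEnsemble(spec, names, est)
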