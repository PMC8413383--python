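"""Regression model library behind one uniform fit/predict contract.

Registered families: ``glm``, ``ridge``, ``lasso``, ``gam``, ``mars``
(degree 1/2/3 variants), ``random_forest``, ``gbm``, ``bart``. All are
addressed by family name through :func:`fit`; :func:`default_specs` yields
the registered variants with documented default hyperparameters.
"""

from __future__ import annotations

import warnings

import numpy as np

from .base import (
    ConfigurationError,
    FitError,
    FittedModel,
    ModelSpec,
    fit,
    registered_families,
)
from . import linear, gam, mars, ensembles, bart  # noqa: F401  (register families)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "FitError",
    "ConfigurationError",
    "fit",
    "registered_families",
    "default_specs",
    "importance",
]


def default_specs(seed: int = 0, families: list[str] | None = None) -> list[ModelSpec]:
    """The registered library variants with their default hyperparameters.

    MARS is registered at interaction degrees 1, 2 and 3 (pruning penalty 2
    for each); every stochastic family receives a seed derived from
    ``seed``.
    """
    specs = [
        ModelSpec.make("glm", seed=seed),
        ModelSpec.make("ridge", seed=seed, alpha=1.0),
        ModelSpec.make("lasso", seed=seed, alpha=0.01),
        ModelSpec.make("gam", seed=seed),
        ModelSpec.make("mars", seed=seed, label="mars_deg1", degree=1, penalty=2.0),
        ModelSpec.make("mars", seed=seed, label="mars_deg2", degree=2, penalty=2.0),
        ModelSpec.make("mars", seed=seed, label="mars_deg3", degree=3, penalty=2.0),
        ModelSpec.make("random_forest", seed=seed),
        ModelSpec.make("gbm", seed=seed),
        ModelSpec.make("bart", seed=seed),
    ]
    if families is not None:
        specs = [s for s in specs if s.family in families or s.name in families]
    return specs


def importance(
    model: FittedModel, table=None, seed: int = 0, n_repeats: int = 10
) -> dict[str, float]:
    """Per-predictor importance scores, normalized to sum to one.

    Tree ensembles report their native split-based scores (for the Bayesian
    ensemble, inclusion proportions of the splitting rules). Families
    without a native score fall back to permutation importance on the
    supplied table, with a warning.
    """
    native = model.importance()
    if native is not None:
        return native
    if table is None:
        raise ConfigurationError(
            f"{model.spec.name} has no native importance; pass a table for the "
            "permutation fallback"
        )
    warnings.warn(
        f"{model.spec.name}: no native importance; using permutation importance"
    )
    rng = np.random.default_rng(seed)
    X = table.df[model.columns].to_numpy(float)
    y = table.df[table.response_name].to_numpy(float)
    base_mse = float(np.mean((model.predict(table.df[model.columns]) - y) ** 2))
    scores = np.zeros(len(model.columns))
    for j in range(len(model.columns)):
        worsening = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            mse = float(np.mean((model.predict(Xp) - y) ** 2))
            worsening += mse - base_mse
        scores[j] = max(worsening / n_repeats, 0.0)
    if scores.sum() == 0:
        scores[:] = 1.0
    scores = scores / scores.sum()
    return dict(zip(model.columns, scores))
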