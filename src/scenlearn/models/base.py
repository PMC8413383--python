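"""Uniform fit/predict contract for the regression model library.

Every learner in the library sits behind the same small surface so that the
selection harness, the partial-dependence engine and the scenario engine
never need to know which family they are driving:

* ``fit(spec, table, train_index)`` returns a :class:`FittedModel`;
* ``FittedModel.predict(X)`` maps a predictor frame to point predictions;
* ``FittedModel.importance()`` optionally returns per-predictor scores that
  are non-negative and sum to one;
* ``FittedModel.predict_draws(X)`` optionally exposes posterior draws
  (the Bayesian tree ensemble uses this for its credible bands).
"""

from __future__ import annotations

import pickle
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class FitError(RuntimeError):
    """A model family failed to fit (e.g. singular design)."""


class ConfigurationError(ValueError):
    """Unknown family or invalid hyperparameters."""


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameters and seed.

    ``family`` must name a registered family; ``hyperparams`` are passed to
    the family's constructor; ``seed`` feeds every stochastic family.
    ``label`` distinguishes registered variants of one family (e.g. MARS
    degree variants) in reports.
    """

    family: str
    hyperparams: tuple = ()
    seed: int = 0
    label: str | None = None

    @property
    def name(self) -> str:
        return self.label or self.family

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    @staticmethod
    def make(family: str, seed: int = 0, label: str | None = None, **hyperparams) -> "ModelSpec":
        return ModelSpec(
            family=family,
            hyperparams=tuple(sorted(hyperparams.items())),
            seed=seed,
            label=label,
        )


class FittedModel(ABC):
    """A trained member of the model library."""

    def __init__(self, spec: ModelSpec, columns: Sequence[str]):
        self.spec = spec
        self.columns = list(columns)

    def _check_columns(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.columns if c not in X.columns]
            if missing:
                raise ConfigurationError(
                    f"prediction input is missing training columns: {missing}"
                )
            return X[self.columns].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != len(self.columns):
            raise ConfigurationError(
                f"expected {len(self.columns)} predictor columns, got shape {X.shape}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        arr = self._check_columns(X)
        out = np.asarray(self._predict(arr), float).ravel()
        if not np.all(np.isfinite(out)):
            raise FitError(f"{self.spec.name}: non-finite predictions")
        return out

    @abstractmethod
    def _predict(self, X: np.ndarray) -> np.ndarray: ...

    # optional contracts -------------------------------------------------
    def importance(self) -> dict[str, float] | None:
        """Native per-predictor importance scores (sum to 1), or None."""
        return None

    def predict_draws(self, X) -> np.ndarray | None:
        """Posterior draws of the regression function, shape (draws, rows)."""
        return None

    def predict_interval(self, X, level: float = 0.95):
        draws = self.predict_draws(X)
        if draws is None:
            return None
        a = (1 - level) / 2
        return (
            np.quantile(draws, a, axis=0),
            np.quantile(draws, 1 - a, axis=0),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "FittedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable] = {}


def register_family(name: str):
    def deco(fn):
        _REGISTRY[name] = fn
        return fn

    return deco


def registered_families() -> list[str]:
    return list(_REGISTRY)


def fit(spec: ModelSpec, table, train_index=None) -> FittedModel:
    """Fit one library member on (a subset of) a feature table."""
    if spec.family not in _REGISTRY:
        raise ConfigurationError(
            f"unknown model family {spec.family!r}; registered: {sorted(_REGISTRY)}"
        )
    df = table.df if train_index is None else table.df.iloc[np.asarray(train_index)]
    if len(df) == 0:
        raise FitError("empty training index")
    X = df[table.predictor_names].to_numpy(float)
    y = df[table.response_name].to_numpy(float)
    return _REGISTRY[spec.family](spec, X, y, table.predictor_names)
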