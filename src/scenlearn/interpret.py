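"""Partial dependence and variable-importance ranking for a fitted model.

The partial effect of predictor ``x_j`` at grid value ``v`` is the model's
prediction averaged over the empirical distribution of the remaining
predictors:

    p_j(v) = (1/n) * sum_i f(v, x_{-j,i}),

i.e. every background row is cloned, its j-th column overwritten with
``v``, and the predictions averaged. Uncertainty bands come from posterior
draws when the model exposes them, otherwise from a nonparametric
bootstrap over the background rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable
from .models import FittedModel, importance as _model_importance


@dataclass
class PDPResult:
    predictor: str
    grid: np.ndarray
    effect: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    n_background: int = 0
    band_source: str | None = None  # 'posterior' | 'bootstrap'

    def frame(self) -> pd.DataFrame:
        d = {"grid": self.grid, "effect": self.effect}
        if self.lower is not None:
            d["lower"], d["upper"] = self.lower, self.upper
        return pd.DataFrame(d)

    def write_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.effect, color="black")
        if self.lower is not None:
            ax.plot(self.grid, self.lower, color="tab:blue", lw=0.8)
            ax.plot(self.grid, self.upper, color="tab:blue", lw=0.8)
        ax.set_xlabel(self.predictor)
        ax.set_ylabel("partial effect on K")
        return ax


def default_grid(table: FeatureTable, predictor: str, n_points: int = 25) -> np.ndarray:
    """Equally spaced quantiles (q0.01..q0.99) of the observed predictor."""
    x = table.df[predictor].to_numpy(float)
    grid = np.unique(np.quantile(x, np.linspace(0.01, 0.99, n_points)))
    return grid


def _pdp_matrix(
    model: FittedModel, table: FeatureTable, predictor: str, grid: np.ndarray
) -> np.ndarray:
    """Predictions P[g, i]: row i with predictor forced to grid[g]."""
    X = table.df[model.columns].copy()
    n = len(X)
    big = pd.concat([X] * len(grid), ignore_index=True)
    big[predictor] = np.repeat(grid, n)
    preds = model.predict(big)
    return preds.reshape(len(grid), n)


def compute_pdp(
    model: FittedModel,
    table: FeatureTable,
    predictor: str,
    grid=None,
) -> PDPResult:
    """Partial dependence of the model on one predictor over a grid."""
    if predictor not in model.columns:
        raise ValueError(f"{predictor!r} is not a model input")
    grid = default_grid(table, predictor) if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if not np.all(np.diff(grid) > 0) and grid.size > 1:
        grid = np.unique(grid)
    x = table.df[predictor].to_numpy(float)
    if grid.min() < x.min() or grid.max() > x.max():
        warnings.warn(
            f"PDP grid for {predictor!r} extends beyond the observed range "
            "(extrapolation)"
        )
    P = _pdp_matrix(model, table, predictor, grid)
    return PDPResult(
        predictor=predictor,
        grid=grid,
        effect=P.mean(axis=1),
        n_background=P.shape[1],
    )


def pdp_band(
    model: FittedModel,
    table: FeatureTable,
    predictor: str,
    grid=None,
    level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> PDPResult:
    """Partial dependence with a pointwise uncertainty band.

    Posterior draws back the band when the model exposes them; otherwise a
    nonparametric bootstrap over the background rows (``n_boot`` resamples
    of the averaging set) is used.
    """
    res = compute_pdp(model, table, predictor, grid)
    grid_arr = res.grid
    a = (1 - level) / 2
    X = table.df[model.columns].copy()
    n = len(X)
    big = pd.concat([X] * len(grid_arr), ignore_index=True)
    big[predictor] = np.repeat(grid_arr, n)
    draws = model.predict_draws(big)
    if draws is not None:
        # draw-wise PDP: average each posterior draw over the background rows
        per_draw = draws.reshape(draws.shape[0], len(grid_arr), n).mean(axis=2)
        res.lower = np.quantile(per_draw, a, axis=0)
        res.upper = np.quantile(per_draw, 1 - a, axis=0)
        res.band_source = "posterior"
        res.effect = per_draw.mean(axis=0)
        return res
    if n_boot <= 1:
        # a single resample carries no spread: degenerate band at the estimate
        res.lower = res.effect.copy()
        res.upper = res.effect.copy()
        res.band_source = "bootstrap"
        return res
    P = model.predict(big).reshape(len(grid_arr), n)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = P[:, idx].mean(axis=2)  # (grid, n_boot)
    res.lower = np.minimum(np.quantile(boot, a, axis=1), res.effect)
    res.upper = np.maximum(np.quantile(boot, 1 - a, axis=1), res.effect)
    res.band_source = "bootstrap"
    return res


def rank_variables(
    model: FittedModel, table: FeatureTable | None = None, seed: int = 0
) -> pd.Series:
    """Importance scores, descending, normalized to sum to one (stable ties)."""
    scores = _model_importance(model, table=table, seed=seed)
    s = pd.Series(scores, dtype=float)
    return s.sort_values(ascending=False, kind="stable")
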