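"""Repeated 80-20 randomized-holdout model comparison and selection.

Each of ``repeats`` (default 30) rounds draws a fresh random 80% training /
20% holdout split; every library member is fitted on the training rows and
scored in- and out-of-sample with R-squared, RMSE and MAE. A null model
that always predicts the training mean of the response anchors the
comparison. The best model minimizes mean out-of-sample RMSE, with ties
broken by out-of-sample MAE, then in-sample RMSE, then registry order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .data import FeatureTable
from .models import FittedModel, ModelSpec

logger = logging.getLogger(__name__)

NULL_NAME = "null"


@dataclass(frozen=True)
class SplitPlan:
    repeat_index: int
    train: np.ndarray
    test: np.ndarray
    seed: int


def make_splits(n: int, repeats: int, seed: int) -> list[SplitPlan]:
    """Draw ``repeats`` random 80/20 holdout splits of ``n`` rows.

    The training size is ``round(0.8 n)`` with at least one test row.
    After drawing, coverage is checked: every row must appear in at least
    one training set; in the vanishingly unlikely event it does not, the
    whole plan is re-drawn from the next seed (logged).
    """
    if n < 5:
        raise ValueError(f"need at least 5 rows for an 80-20 split, got {n}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n_train = int(round(0.8 * n))
    n_train = min(n_train, n - 1)
    coverage_possible = repeats * n_train >= n
    if not coverage_possible:
        logger.warning(
            "%d repeats of %d training rows cannot cover all %d rows; "
            "coverage check skipped",
            repeats,
            n_train,
            n,
        )
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        plans = []
        covered = np.zeros(n, bool)
        for r in range(repeats):
            perm = rng.permutation(n)
            train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            covered[train] = True
            plans.append(SplitPlan(repeat_index=r + 1, train=train, test=test, seed=seed))
        if covered.all() or not coverage_possible:
            if attempt:
                logger.info("split coverage achieved after %d re-draws", attempt)
            return plans
        logger.warning("re-drawing splits: %d rows never trained on", (~covered).sum())
    raise RuntimeError("could not achieve training coverage")  # pragma: no cover


def score(y, yhat) -> dict[str, float]:
    """R-squared, RMSE and MAE of predictions against observations.

    With a zero-variance ``y`` the R-squared is undefined and returned as
    NaN with a warning; RMSE and MAE are still returned.
    """
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) != len(yhat):
        raise ValueError("y and yhat must have equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero-variance response: R^2 is undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / sst
    return {"r2": r2, "rmse": rmse, "mae": mae}


@dataclass
class CVReport:
    """Per-(model, repeat) scores plus per-model aggregates.

    ``cells`` is tidy: one row per (model, repeat, sample) where sample is
    ``in``/``out``. ``failures`` records fits that errored (the harness
    continues). ``full_fit_r2`` holds the in-sample R-squared of each
    model refitted on all rows, the single goodness-of-fit column of the
    comparison table.
    """

    cells: pd.DataFrame
    specs: list[ModelSpec]
    failures: list[dict] = field(default_factory=list)
    full_fit_r2: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Model-comparison table: per model, mean and SD of each metric."""
        agg = (
            self.cells.pivot_table(
                index="model",
                columns="sample",
                values=["r2", "rmse", "mae"],
                aggfunc=["mean", "std"],
            )
        )
        agg.columns = [f"{m}_{s}_{a}" for a, m, s in agg.columns]
        order = [s.name for s in self.specs] + [NULL_NAME]
        agg = agg.reindex([m for m in order if m in agg.index])
        if self.full_fit_r2:
            agg.insert(0, "r2_full_fit", pd.Series(self.full_fit_r2))
        # the null model's R^2 against its own mean is 0 by construction,
        # not a goodness of fit; report it as not applicable
        if NULL_NAME in agg.index:
            for c in agg.columns:
                if c.startswith("r2"):
                    agg.loc[NULL_NAME, c] = np.nan
        return agg

    def write_csv(self, path) -> None:
        self.summary().to_csv(path)

    def write_json(self, path) -> None:
        import json

        payload = {
            "cells": self.cells.to_dict(orient="records"),
            "failures": self.failures,
            "full_fit_r2": self.full_fit_r2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class _NullModel:
    """Predicts the training mean of the response, whatever the input."""

    def __init__(self, mean: float):
        self.mean = mean

    def predict(self, X):
        return np.full(len(X), self.mean)


def run_cv(
    table: FeatureTable,
    specs: list[ModelSpec],
    plans: list[SplitPlan],
    include_null: bool = True,
    full_refit: bool = True,
) -> CVReport:
    """Score every (model spec, split) cell; failures are recorded, not fatal."""
    if not specs:
        raise ValueError("specs must be non-empty")
    y_all = table.y.to_numpy(float)
    X_all = table.X
    rows, failures = [], []
    named_specs = list(specs)
    for spec in named_specs:
        for plan in plans:
            try:
                model = models.fit(spec, table, plan.train)
            except Exception as exc:  # recorded, harness continues
                failures.append(
                    {"model": spec.name, "repeat": plan.repeat_index, "error": str(exc)}
                )
                continue
            for sample, idx in (("in", plan.train), ("out", plan.test)):
                s = score(y_all[idx], model.predict(X_all.iloc[idx]))
                rows.append(
                    {"model": spec.name, "repeat": plan.repeat_index, "sample": sample, **s}
                )
    if include_null:
        for plan in plans:
            null = _NullModel(float(y_all[plan.train].mean()))
            for sample, idx in (("in", plan.train), ("out", plan.test)):
                s = score(y_all[idx], null.predict(X_all.iloc[idx]))
                rows.append(
                    {"model": NULL_NAME, "repeat": plan.repeat_index, "sample": sample, **s}
                )
    report = CVReport(cells=pd.DataFrame(rows), specs=named_specs, failures=failures)
    if full_refit:
        for spec in named_specs:
            try:
                model = models.fit(spec, table)
                report.full_fit_r2[spec.name] = score(y_all, model.predict(X_all))["r2"]
            except Exception as exc:
                failures.append({"model": spec.name, "repeat": "full", "error": str(exc)})
    return report


def select_best(report: CVReport) -> ModelSpec:
    """The spec minimizing mean out-of-sample RMSE (documented tie-breaks)."""
    cells = report.cells
    ranked = []
    for i, spec in enumerate(report.specs):
        sub = cells[(cells["model"] == spec.name)]
        out = sub[sub["sample"] == "out"]
        if out.empty:
            continue
        ranked.append(
            (
                float(out["rmse"].mean()),
                float(out["mae"].mean()),
                float(sub[sub["sample"] == "in"]["rmse"].mean()),
                i,
                spec,
            )
        )
    if not ranked:
        raise RuntimeError("every model family failed to fit")
    ranked.sort(key=lambda t: t[:4])
    if len(ranked) > 1 and ranked[0][:3] == ranked[1][:3]:
        logger.info(
            "tie between %s and %s broken by registry order",
            ranked[0][4].name,
            ranked[1][4].name,
        )
    return ranked[0][4]
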