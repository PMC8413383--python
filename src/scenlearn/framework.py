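"""Top-level modelling API in the model/results idiom.

:class:`CommunityOutcomeModel` is built from a community feature table (or
a plain DataFrame plus column metadata); ``fit()`` runs the repeated
80-20 holdout comparison across the model library, refits the winner on
all rows, and returns a :class:`CommunityOutcomeResults` carrying the
comparison table, the selected model, variable importances and methods for
partial dependence and scenario analysis.

    >>> table, truth = synthetic.generate(seed=1)          # doctest: +SKIP
    >>> res = CommunityOutcomeModel(table).fit(seed=1)     # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
"""

from __future__ import annotations

import pandas as pd

from . import models
from .data import ColumnMeta, FeatureTable, reduce_preclinical
from .interpret import PDPResult, compute_pdp, pdp_band, rank_variables
from .scenario import (
    ScenarioSpec,
    Verdict,
    adjudicate,
    default_hypotheses,
    fit_group_distributions,
    run_scenario,
)
from .selection import CVReport, make_splits, run_cv, select_best


class CommunityOutcomeModel:
    """Scenario-based predictive model of a grouped community outcome."""

    def __init__(
        self,
        table: FeatureTable,
        reduce_preclinical_block: bool = True,
        variance_threshold: float = 0.92,
    ):
        if reduce_preclinical_block:
            table, self.reduction_ = reduce_preclinical(table, variance_threshold)
        else:
            self.reduction_ = None
        self.table = table

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, meta: list[ColumnMeta], **kwargs
    ) -> "CommunityOutcomeModel":
        return cls(FeatureTable(df=df.reset_index(drop=True), meta=list(meta)), **kwargs)

    def fit(
        self,
        families: list[str] | None = None,
        repeats: int = 30,
        seed: int = 0,
    ) -> "CommunityOutcomeResults":
        specs = models.default_specs(seed=seed, families=families)
        plans = make_splits(self.table.n, repeats, seed)
        report = run_cv(self.table, specs, plans)
        selected = select_best(report)
        fitted = models.fit(selected, self.table)
        return CommunityOutcomeResults(self, report, selected, fitted, seed)


class CommunityOutcomeResults:
    """Fitted selection results plus interpretation and scenario methods."""

    def __init__(self, model: CommunityOutcomeModel, cv_report: CVReport,
                 selected_spec, fitted, seed: int):
        self.model = model
        self.table = model.table
        self.cv_report = cv_report
        self.selected_spec = selected_spec
        self.fitted = fitted
        self.seed = seed
        self._fits_cache: dict = {}

    # -- inference --------------------------------------------------------
    def importance(self) -> pd.Series:
        return rank_variables(self.fitted, self.table, seed=self.seed)

    def partial_dependence(
        self, predictor: str, grid=None, band: bool = True, **kw
    ) -> PDPResult:
        if band:
            return pdp_band(self.fitted, self.table, predictor, grid,
                            seed=self.seed, **kw)
        return compute_pdp(self.fitted, self.table, predictor, grid)

    # -- scenarios --------------------------------------------------------
    def _distribution_fits(self, variables):
        key = tuple(sorted(variables))
        if key not in self._fits_cache:
            self._fits_cache[key] = fit_group_distributions(self.table, key)
        return self._fits_cache[key]

    def run_scenario(self, spec: ScenarioSpec):
        fits = self._distribution_fits(spec.variables)
        return run_scenario(self.fitted, self.table, spec, fits, seed=self.seed)

    def run_hypotheses(
        self, specs: list[ScenarioSpec] | None = None
    ) -> dict[str, Verdict]:
        specs = specs or default_hypotheses(self.table)
        out = {}
        for spec in specs:
            res = self.run_scenario(spec)
            out[spec.hypothesis_id] = adjudicate(res, spec)
        return out

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        s = self.cv_report.summary()
        cols = [c for c in ["r2_full_fit", "rmse_in_mean", "rmse_out_mean",
                            "mae_in_mean", "mae_out_mean"] if c in s.columns]
        lines = [
            "Community outcome model selection (repeated 80-20 holdout)",
            "=" * 62,
            f"rows: {self.table.n}   groups: {self.table.groups.nunique()}   "
            f"repeats: {self.cv_report.cells['repeat'].max()}",
            f"selected model: {self.selected_spec.name}",
            "-" * 62,
            s[cols].round(4).to_string(),
        ]
        if self.cv_report.failures:
            lines.append(f"failed fits: {len(self.cv_report.failures)}")
        return "\n".join(lines)
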