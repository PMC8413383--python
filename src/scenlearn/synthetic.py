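"""Synthetic multilevel community datasets with known ground truth.

The generator emulates the structure the framework assumes: ~50 groups
(states) of metropolitan communities; grouped predictors with known
per-group parametric marginals for each built-environment category;
a block of correlated pre-clinical health variables driven by a few latent
factors; and a known response surface (linear, interaction and smooth
saturating terms) plus additive Gaussian noise, with the response K
centred near 13% and clipped to [0, 100].

The returned :class:`GroundTruth` records the surface, the true per-group
marginal parameters and closed-form partial effects for additive terms, so
every downstream stage can be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ColumnMeta, FeatureTable
from .scenario import _frozen, _mom_params

RESPONSE = "poor_mental_health_pct"
GROUP = "state"


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal family and per-group parameter ranges for one predictor."""

    name: str
    category: str
    family: str = "normal"  # normal | gamma | lognormal | uniform
    mean_range: tuple[float, float] = (0.0, 1.0)
    sd_range: tuple[float, float] = (0.5, 1.0)
    bounds: tuple[float, float] | None = (0.0, 100.0)


@dataclass(frozen=True)
class Term:
    """One additive piece of the response surface.

    kinds: 'linear' (coef*x), 'quadratic' (coef*x^2), 'saturating'
    (coef*min(x, threshold): the effect plateaus beyond the threshold) and
    'interaction' (coef*x1*x2).
    """

    kind: str
    variables: tuple[str, ...]
    coef: float
    threshold: float | None = None

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        if self.kind == "linear":
            return self.coef * df[self.variables[0]].to_numpy(float)
        if self.kind == "quadratic":
            return self.coef * df[self.variables[0]].to_numpy(float) ** 2
        if self.kind == "saturating":
            x = df[self.variables[0]].to_numpy(float)
            return self.coef * np.minimum(x, self.threshold)
        if self.kind == "interaction":
            x1 = df[self.variables[0]].to_numpy(float)
            x2 = df[self.variables[1]].to_numpy(float)
            return self.coef * x1 * x2
        raise ValueError(f"unknown term kind {self.kind!r}")

    def evaluate_at(self, v: float) -> float:
        """Closed form for single-variable terms at one grid value."""
        one = pd.DataFrame({self.variables[0]: [v]})
        return float(self.evaluate(one)[0])


@dataclass
class GeneratorConfig:
    n_groups: int = 50
    communities_per_group: tuple[int, int] = (5, 50)  # inclusive range
    predictors: tuple[PredictorSpec, ...] = ()
    n_preclinical: int = 12
    n_latent_factors: int = 3
    loading_scale: float = 1.0
    preclinical_noise_sd: float = 0.25
    intercept: float = 6.8
    terms: tuple[Term, ...] = ()
    noise_sd: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.communities_per_group
        if lo < 1 or hi < lo:
            raise ValueError("infeasible communities_per_group range")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names")
        for p in self.predictors:
            if p.family not in ("normal", "gamma", "lognormal", "uniform"):
                raise ValueError(f"unsupported family {p.family!r} for {p.name!r}")
            if p.mean_range[0] > p.mean_range[1] or p.sd_range[0] > p.sd_range[1]:
                raise ValueError(f"infeasible parameter range for {p.name!r}")
        known = set(names) | {
            f"preclin_{i + 1:02d}" for i in range(self.n_preclinical)
        }
        for t in self.terms:
            for v in t.variables:
                if v not in known:
                    raise ValueError(f"surface term references unknown predictor {v!r}")


def default_config(**overrides) -> GeneratorConfig:
    """The default synthetic study: 50 states, 5-50 communities each.

    Coefficients are scaled so the response sits near the observed national
    level of ~13% with a signal-to-noise ratio comfortably above 3.
    """
    predictors = (
        PredictorSpec("poverty_rate", "economic", "normal", (10, 25), (2, 4)),
        PredictorSpec("unemployment_rate", "economic", "gamma", (4, 10), (1, 2.5)),
        PredictorSpec("median_income_k", "economic", "normal", (45, 70), (5, 10), (5, 250)),
        PredictorSpec("no_insurance_pct", "insurance_availability", "normal", (8, 20), (2, 4)),
        PredictorSpec("public_insurance_pct", "insurance_type", "normal", (20, 40), (3, 6)),
        PredictorSpec("transport_cost_pct", "transport_cost", "normal", (15, 30), (2, 5)),
        PredictorSpec("housing_vacancy_pct", "housing_vacancy", "gamma", (5, 15), (2, 4)),
        PredictorSpec("smoking_pct", "behavioral", "normal", (12, 25), (2, 4)),
    )
    terms = (
        Term("linear", ("poverty_rate",), 0.20),
        Term("linear", ("unemployment_rate",), 0.15),
        Term("linear", ("median_income_k",), -0.04),
        Term("linear", ("no_insurance_pct",), 0.08),
        Term("linear", ("public_insurance_pct",), -0.03),
        Term("linear", ("transport_cost_pct",), 0.04),
        Term("saturating", ("housing_vacancy_pct",), 0.12, 12.0),
        Term("linear", ("smoking_pct",), 0.10),
        Term("linear", ("preclin_01",), 0.30),
    )
    cfg = GeneratorConfig(predictors=predictors, terms=terms)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    intercept: float
    terms: tuple[Term, ...]
    noise_sd: float
    group_params: dict  # (group, variable) -> {'family', 'mean', 'sd'}
    clip_rate: float
    predictors_df: pd.DataFrame = field(repr=False, default=None)

    def signal(self, df: pd.DataFrame) -> np.ndarray:
        out = np.full(len(df), self.intercept)
        for t in self.terms:
            out += t.evaluate(df)
        return out

    def additive_terms(self, predictor: str) -> list[Term]:
        own = [t for t in self.terms if predictor in t.variables]
        if any(len(t.variables) > 1 for t in own):
            raise ValueError(
                f"{predictor!r} enters an interaction; no closed-form partial effect"
            )
        return own

    def true_pdp(self, predictor: str, grid) -> np.ndarray:
        """Analytic partial effect for a predictor with additive terms only."""
        grid = np.asarray(grid, float)
        own = self.additive_terms(predictor)
        others = [t for t in self.terms if predictor not in t.variables]
        base = self.intercept + sum(
            float(t.evaluate(self.predictors_df).mean()) for t in others
        )
        return np.array([base + sum(t.evaluate_at(v) for t in own) for v in grid])


def true_pdp(truth: GroundTruth, predictor: str, grid) -> np.ndarray:
    return truth.true_pdp(predictor, grid)


def generate(config: GeneratorConfig | None = None, seed: int | None = None):
    """Draw one synthetic study; returns ``(FeatureTable, GroundTruth)``."""
    cfg = config or default_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    lo, hi = cfg.communities_per_group
    sizes = rng.integers(lo, hi + 1, size=cfg.n_groups)
    groups = [f"S{g + 1:02d}" for g in range(cfg.n_groups)]
    group_col = np.repeat(groups, sizes)
    n = int(sizes.sum())

    data: dict[str, np.ndarray] = {GROUP: group_col}
    group_params: dict = {}
    clipped = total = 0
    for p in cfg.predictors:
        col = np.empty(n)
        pos = 0
        for g, size in zip(groups, sizes):
            mean = rng.uniform(*p.mean_range)
            sd = rng.uniform(*p.sd_range)
            params = _mom_params(
                {"normal": "normal", "gamma": "gamma", "lognormal": "lognormal",
                 "uniform": "uniform"}[p.family],
                mean,
                sd**2,
            )
            dist = _frozen(p.family, params)
            vals = dist.ppf(rng.uniform(size=size))
            if p.bounds is not None:
                clipped += int(np.sum((vals < p.bounds[0]) | (vals > p.bounds[1])))
                total += size
                vals = np.clip(vals, *p.bounds)
            col[pos:pos + size] = vals
            pos += size
            group_params[(g, p.name)] = {"family": p.family, "mean": mean, "sd": sd}
        data[p.name] = col

    # correlated pre-clinical block: few latent factors + small noise
    preclin_names = [f"preclin_{i + 1:02d}" for i in range(cfg.n_preclinical)]
    if cfg.n_preclinical:
        Z = rng.standard_normal((n, cfg.n_latent_factors))
        L = rng.standard_normal((cfg.n_preclinical, cfg.n_latent_factors))
        L *= cfg.loading_scale / np.linalg.norm(L, axis=1, keepdims=True)
        block = Z @ L.T + cfg.preclinical_noise_sd * rng.standard_normal(
            (n, cfg.n_preclinical)
        )
        for i, name in enumerate(preclin_names):
            data[name] = block[:, i]

    df = pd.DataFrame(data)
    truth = GroundTruth(
        intercept=cfg.intercept,
        terms=cfg.terms,
        noise_sd=cfg.noise_sd,
        group_params=group_params,
        clip_rate=clipped / total if total else 0.0,
        predictors_df=None,
    )
    signal = truth.signal(df)
    y = signal + cfg.noise_sd * rng.standard_normal(n)
    n_clip_y = int(np.sum((y < 0) | (y > 100)))
    if n_clip_y:
        import logging

        logging.getLogger(__name__).info(
            "response clipped to [0,100] for %d of %d rows", n_clip_y, n
        )
    df[RESPONSE] = np.clip(y, 0.0, 100.0)

    meta = [ColumnMeta(GROUP, "group_key")]
    for p in cfg.predictors:
        meta.append(ColumnMeta(p.name, "predictor", p.category, bounds=p.bounds))
    for name in preclin_names:
        meta.append(ColumnMeta(name, "predictor", "preclinical"))
    meta.append(ColumnMeta(RESPONSE, "response", bounds=(0.0, 100.0)))

    table = FeatureTable(df=df[[m.name for m in meta]], meta=meta)
    truth.predictors_df = table.df[table.predictor_names].copy()
    return table, truth


def write_fixture(directory, config: GeneratorConfig | None = None, seed: int = 0):
    """Emit a small versioned CSV + metadata config pair for tests/demos."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table, truth = generate(config, seed=seed)
    table.write_csv(directory / "communities.csv")
    cols = []
    for m in table.meta:
        cols.append(
            {
                "name": m.name,
                "role": m.role,
                **({"category": m.category} if m.category else {}),
                **({"bounds": list(m.bounds)} if m.bounds else {}),
            }
        )
    (directory / "columns.json").write_text(json.dumps({"columns": cols}, indent=1))
    return table, truth
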