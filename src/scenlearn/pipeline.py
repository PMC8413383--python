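"""End-to-end orchestration: load -> reduce -> select -> interpret -> scenarios.

Every stage writes its artifacts (CSV/JSON) under the configured output
directory, along with a run manifest recording seeds, package version and
a hash of the effective configuration, so a run is reproducible and
auditable. Stage seeds fan out deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, models
from .data import FeatureTable, load_feature_table, meta_from_config, reduce_preclinical
from .interpret import compute_pdp, pdp_band, rank_variables
from .scenario import (
    ScenarioSpec,
    adjudicate,
    default_hypotheses,
    fit_group_distributions,
    run_scenario,
)
from .selection import make_splits, run_cv, select_best
from . import synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    csv_path: str | None = None
    meta_path: str | None = None
    use_synthetic: bool = False
    synthetic_overrides: dict = field(default_factory=dict)
    families: list[str] | None = None
    repeats: int = 30
    train_fraction: float = 0.8
    variance_threshold: float = 0.92
    pdp_predictors: list[str] | None = None  # None -> top 4 by importance
    pdp_bands: bool = True
    scenarios: list[dict] | None = None  # None -> default H1..H10 battery
    scenario_sign_map: dict | None = None
    n_draws: int = 1000
    seed: int = 0
    outdir: str = "scenlearn_run"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig(**cfg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    return int((master * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class RunArtifacts:
    table: FeatureTable
    reduction: object
    cv_report: object
    selected_spec: object
    model: object
    importance: pd.Series
    pdps: dict
    scenario_results: dict
    verdicts: dict
    manifest: dict
    outdir: Path


def _load_table(config: RunConfig) -> FeatureTable:
    if config.use_synthetic or config.csv_path is None:
        gen_cfg = synthetic.default_config(**config.synthetic_overrides)
        table, _ = synthetic.generate(gen_cfg, seed=stage_seed(config.seed, "generate"))
        return table
    meta = meta_from_config(config.meta_path)
    return load_feature_table(config.csv_path, meta)


def _scenario_specs(config: RunConfig, table: FeatureTable) -> list[ScenarioSpec]:
    if config.scenarios is None:
        return default_hypotheses(
            table, sign_map=config.scenario_sign_map, n_draws=config.n_draws
        )
    specs = []
    for s in config.scenarios:
        unknown = [v for v in s["directions"] if v not in table.predictor_names]
        if unknown:
            raise ValueError(f"scenario {s.get('id')}: unknown variables {unknown}")
        specs.append(
            ScenarioSpec.make(
                s["id"], s["directions"], s["expected"], s.get("n_draws", config.n_draws)
            )
        )
    return specs


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute every stage, writing artifacts as it goes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s: %.2fs", stage, timings[stage])

        return _T()

    with timed("load"):
        table = _load_table(config)
        # validate scenario variables before any fitting
        specs_scn = _scenario_specs(config, table)
        table.write_csv(outdir / "table.csv")

    with timed("reduce"):
        table, reduction = reduce_preclinical(table, config.variance_threshold)
        if reduction is not None:
            reduction.write_csv(outdir / "pca_loadings.csv")
        else:
            warnings_log.append("PCA reduction skipped (fewer than 2 pre-clinical columns)")

    with timed("select"):
        model_specs = models.default_specs(
            seed=stage_seed(config.seed, "models"), families=config.families
        )
        plans = make_splits(table.n, config.repeats, stage_seed(config.seed, "splits"))
        cv_report = run_cv(table, model_specs, plans)
        cv_report.write_csv(outdir / "cv_report.csv")
        cv_report.write_json(outdir / "cv_report.json")
        for f in cv_report.failures:
            warnings_log.append(f"fit failure: {f}")
        selected = select_best(cv_report)
        model = models.fit(selected, table)
        (outdir / "selected_model.json").write_text(
            json.dumps(
                {"family": selected.family, "name": selected.name,
                 "hyperparams": selected.params, "seed": selected.seed},
                indent=1,
            )
        )

    with timed("interpret"):
        imp = rank_variables(model, table, seed=stage_seed(config.seed, "importance"))
        imp.rename("importance").to_csv(outdir / "importance.csv")
        predictors = config.pdp_predictors or list(imp.index[:4])
        pdps = {}
        for pred in predictors:
            if config.pdp_bands:
                res = pdp_band(
                    model, table, pred, seed=stage_seed(config.seed, f"pdp:{pred}")
                )
            else:
                res = compute_pdp(model, table, pred)
            res.write_csv(outdir / f"pdp_{pred}.csv")
            pdps[pred] = res

    with timed("scenario"):
        scn_vars = sorted({v for s in specs_scn for v in s.variables})
        fits = fit_group_distributions(table, scn_vars)
        results, verdicts = {}, {}
        rows = []
        for spec in specs_scn:
            res = run_scenario(
                model, table, spec, fits, seed=stage_seed(config.seed, "scenario")
            )
            results[spec.hypothesis_id] = res
            verdicts[spec.hypothesis_id] = adjudicate(res, spec)
            if res.clip_rate:
                warnings_log.append(
                    f"{spec.hypothesis_id}: {100 * res.clip_rate:.2f}% of draws clipped"
                )
            pg = res.per_group.copy()
            pg.insert(0, "hypothesis", spec.hypothesis_id)
            rows.append(pg)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                outdir / "scenario_results.csv", index=False
            )
            national = {
                hid: {
                    "expected": v.expected,
                    "mean_delta_k": v.national_mean_delta_k,
                    "classification": v.classification,
                    "nationally_supported": v.nationally_supported,
                    "nonconforming_groups": v.nonconforming_groups,
                }
                for hid, v in verdicts.items()
            }
            (outdir / "scenario_national.json").write_text(
                json.dumps(national, indent=1)
            )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_rows": table.n,
        "n_groups": int(table.groups.nunique()),
        "selected_model": selected.name,
        "timings_s": timings,
        "warnings": warnings_log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    artifacts = RunArtifacts(
        table=table,
        reduction=reduction,
        cv_report=cv_report,
        selected_spec=selected,
        model=model,
        importance=imp,
        pdps=pdps,
        scenario_results=results,
        verdicts=verdicts,
        manifest=manifest,
        outdir=outdir,
    )
    write_report(artifacts)
    return artifacts


def write_report(artifacts: RunArtifacts) -> Path:
    """Render a human-readable Markdown summary of a run."""
    lines = ["# Community outcome scenario analysis", ""]
    m = artifacts.manifest
    lines += [
        f"- rows: {m['n_rows']}, groups: {m['n_groups']}",
        f"- selected model: **{m['selected_model']}**",
        f"- master seed: {m['seed']}, config hash: `{m['config_hash']}`",
        "",
        "## Model comparison (repeated 80-20 holdout)",
        "",
    ]
    summary = artifacts.cv_report.summary()
    cols = [c for c in ["r2_full_fit", "rmse_out_mean", "rmse_in_mean",
                        "mae_out_mean", "mae_in_mean"] if c in summary.columns]
    lines += ["```", summary[cols].round(4).to_string(), "```"]
    if artifacts.cv_report.failures:
        lines += ["", "Failed cells (harness continued):"]
        lines += [f"- {f}" for f in artifacts.cv_report.failures]

    lines += ["", "## Variable importance (top 10)", ""]
    lines += [
        "```",
        artifacts.importance.head(10).round(4).to_frame("score").to_string(),
        "```",
    ]

    if artifacts.pdps:
        lines += ["", "## Partial dependence", ""]
        for name, res in artifacts.pdps.items():
            rng_lo, rng_hi = res.effect.min(), res.effect.max()
            lines.append(
                f"- `{name}`: effect spans {rng_lo:.3f} to {rng_hi:.3f} over the grid"
                + (f" ({res.band_source} band)" if res.band_source else "")
            )

    if artifacts.verdicts:
        lines += ["", "## Scenario hypotheses", ""]
        for hid, v in artifacts.verdicts.items():
            status = "supported" if v.nationally_supported else "not supported"
            lines.append(
                f"- **{hid}** (expected {v.expected}): national mean dK = "
                f"{v.national_mean_delta_k:+.4f} -> {v.classification}; {status}"
                + (
                    f"; nonconforming groups: {', '.join(v.nonconforming_groups)}"
                    if v.nonconforming_groups
                    else ""
                )
            )
    if m["warnings"]:
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in m["warnings"]]
    path = artifacts.outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
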