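"""Community feature tables: schema, validation, CSV I/O and PCA reduction.

A feature table holds one row per metropolitan community, a continuous
response ``K`` (the percentage of adults reporting poor mental health for
more than 14 of the past 30 days, bounded to [0, 100]), a group key (US
state or any grouping label), and predictor columns each tagged with a
category describing which aspect of the built environment or population it
measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

ROLES = {"response", "predictor", "group_key"}
CATEGORIES = {
    "economic",
    "insurance_availability",
    "insurance_type",
    "transport_cost",
    "housing_vacancy",
    "behavioral",
    "preclinical",
    "other",
}


class SchemaError(ValueError):
    """Column metadata or CSV header does not describe a valid table."""


class ValidationError(ValueError):
    """Row-level content violates declared bounds or is not numeric."""


@dataclass(frozen=True)
class ColumnMeta:
    """Declared role, category and validity range of one column."""

    name: str
    role: str
    category: str | None = None
    units: str = ""
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"column {self.name!r}: unknown role {self.role!r}")
        if self.role == "predictor":
            if self.category is None:
                raise SchemaError(f"predictor {self.name!r} has no category")
            if self.category not in CATEGORIES:
                raise SchemaError(
                    f"predictor {self.name!r}: unknown category {self.category!r}"
                )
        if self.bounds is not None and self.bounds[0] > self.bounds[1]:
            raise SchemaError(f"column {self.name!r}: bounds out of order")


def _check_meta(meta: Sequence[ColumnMeta]) -> None:
    roles = [m.role for m in meta]
    if roles.count("response") != 1:
        raise SchemaError("exactly one column must have role='response'")
    if roles.count("group_key") != 1:
        raise SchemaError("exactly one column must have role='group_key'")
    names = [m.name for m in meta]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate column names in metadata")


@dataclass
class FeatureTable:
    """Validated grouped community table.

    Attributes
    ----------
    df : DataFrame with all declared columns.
    meta : column metadata, in column order.
    """

    df: pd.DataFrame
    meta: list[ColumnMeta]

    def __post_init__(self) -> None:
        _check_meta(self.meta)
        self._by_name = {m.name: m for m in self.meta}
        missing = [m.name for m in self.meta if m.name not in self.df.columns]
        if missing:
            raise SchemaError(f"columns missing from data: {missing}")

    # -- column accessors -------------------------------------------------
    @property
    def response_name(self) -> str:
        return next(m.name for m in self.meta if m.role == "response")

    @property
    def group_name(self) -> str:
        return next(m.name for m in self.meta if m.role == "group_key")

    @property
    def predictor_names(self) -> list[str]:
        return [m.name for m in self.meta if m.role == "predictor"]

    def predictors_in_category(self, category: str) -> list[str]:
        return [
            m.name
            for m in self.meta
            if m.role == "predictor" and m.category == category
        ]

    def column_meta(self, name: str) -> ColumnMeta:
        return self._by_name[name]

    @property
    def X(self) -> pd.DataFrame:
        return self.df[self.predictor_names]

    @property
    def y(self) -> pd.Series:
        return self.df[self.response_name]

    @property
    def groups(self) -> pd.Series:
        return self.df[self.group_name]

    @property
    def n(self) -> int:
        return len(self.df)

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        cols = [m.name for m in self.meta]
        self.df[cols].to_csv(path, index=False)

    def with_df(self, df: pd.DataFrame, meta: Sequence[ColumnMeta] | None = None) -> "FeatureTable":
        return FeatureTable(df=df.reset_index(drop=True), meta=list(meta or self.meta))


@dataclass
class PCAReduction:
    """Record of an orthogonal reduction of the pre-clinical block."""

    source_columns: list[str]
    loadings: np.ndarray  # (n_source, n_components), columns orthonormal
    n_components: int
    variance_explained: float  # cumulative fraction at n_components
    explained_ratio: np.ndarray = field(default_factory=lambda: np.array([]))
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    scales: np.ndarray = field(default_factory=lambda: np.array([]))
    component_names: list[str] = field(default_factory=list)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.source_columns, columns=self.component_names
        )

    def write_csv(self, path: str | Path) -> None:
        self.loadings_frame().to_csv(path)


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------

def meta_from_config(path: str | Path) -> list[ColumnMeta]:
    """Read column metadata from a YAML or JSON config file.

    The config is a mapping ``columns: [{name, role, category, units, bounds}]``.
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out = []
    for c in cfg["columns"]:
        bounds = c.get("bounds")
        out.append(
            ColumnMeta(
                name=c["name"],
                role=c["role"],
                category=c.get("category"),
                units=c.get("units", ""),
                bounds=tuple(bounds) if bounds is not None else None,
            )
        )
    _check_meta(out)
    return out


def load_feature_table(csv_path: str | Path, meta: Sequence[ColumnMeta]) -> FeatureTable:
    """Load and validate a community CSV against declared column metadata.

    Raises
    ------
    SchemaError
        If the header is missing declared columns (including the response
        or group key).
    ValidationError
        Naming every offending row for non-numeric cells, missing values,
        or bound violations. Nothing is silently dropped.
    """
    meta = list(meta)
    _check_meta(meta)
    df = pd.read_csv(csv_path)
    missing = [m.name for m in meta if m.name not in df.columns]
    if missing:
        raise SchemaError(f"CSV {csv_path} is missing declared columns: {missing}")
    df = df[[m.name for m in meta]]

    problems: list[str] = []
    for m in meta:
        if m.role == "group_key":
            bad = df.index[df[m.name].isna()].tolist()
            if bad:
                problems.append(f"column {m.name!r}: missing group label at rows {bad}")
            continue
        coerced = pd.to_numeric(df[m.name], errors="coerce")
        bad = df.index[coerced.isna() & df[m.name].notna()].tolist()
        if bad:
            problems.append(f"column {m.name!r}: non-numeric value at rows {bad}")
        nan_rows = df.index[df[m.name].isna()].tolist()
        if nan_rows:
            problems.append(f"column {m.name!r}: missing value at rows {nan_rows}")
        df[m.name] = coerced
        bounds = m.bounds
        if m.role == "response" and bounds is None:
            bounds = (0.0, 100.0)
        if bounds is not None:
            oob = df.index[(coerced < bounds[0]) | (coerced > bounds[1])].tolist()
            if oob:
                problems.append(
                    f"column {m.name!r}: value outside bounds {list(bounds)} at rows {oob}"
                )
    if problems:
        raise ValidationError("; ".join(problems))
    return FeatureTable(df=df.reset_index(drop=True), meta=meta)


# ---------------------------------------------------------------------------
# PCA reduction of the pre-clinical block
# ---------------------------------------------------------------------------

def reduce_preclinical(
    table: FeatureTable, variance_threshold: float = 0.92
) -> tuple[FeatureTable, PCAReduction | None]:
    """Replace correlated pre-clinical columns by principal components.

    Columns tagged ``preclinical`` are standardised (zero mean, unit
    variance) and projected onto the smallest number of principal
    components whose cumulative explained-variance fraction reaches
    ``variance_threshold``. All other columns are untouched. With fewer
    than two pre-clinical columns the table is returned unchanged.
    """
    cols = table.predictors_in_category("preclinical")
    if len(cols) < 2:
        import warnings

        if len(cols) == 1:
            warnings.warn("only one pre-clinical column; PCA reduction skipped")
        return table, None

    Xp = table.df[cols].to_numpy(float)
    means = Xp.mean(axis=0)
    scales = Xp.std(axis=0, ddof=0)
    scales[scales == 0] = 1.0
    Z = (Xp - means) / scales

    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(cols))

    comp_names = [f"preclinical_pc{i + 1}" for i in range(k)]
    reduction = PCAReduction(
        source_columns=cols,
        loadings=pca.components_[:k].T.copy(),
        n_components=k,
        variance_explained=float(cum[k - 1]),
        explained_ratio=pca.explained_variance_ratio_.copy(),
        means=means,
        scales=scales,
        component_names=comp_names,
    )

    new_meta: list[ColumnMeta] = []
    inserted = False
    for m in table.meta:
        if m.name in cols:
            if not inserted:
                for name in comp_names:
                    new_meta.append(
                        ColumnMeta(name=name, role="predictor", category="preclinical")
                    )
                inserted = True
            continue
        new_meta.append(m)

    new_df = table.df.drop(columns=cols).copy()
    for i, name in enumerate(comp_names):
        new_df[name] = scores[:, i]
    new_df = new_df[[m.name for m in new_meta]]
    return FeatureTable(df=new_df, meta=new_meta), reduction
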