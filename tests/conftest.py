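import numpy as np
import pandas as pd
import pytest

from scenlearn.data import ColumnMeta, FeatureTable


def make_table(df: pd.DataFrame, response="k", group="state", categories=None,
               bounds=None):
    """Wrap a DataFrame into a FeatureTable; predictors tagged 'other' unless given."""
    categories = categories or {}
    bounds = bounds or {}
    meta = []
    for col in df.columns:
        if col == response:
            meta.append(ColumnMeta(col, "response", bounds=(0, 100)))
        elif col == group:
            meta.append(ColumnMeta(col, "group_key"))
        else:
            meta.append(
                ColumnMeta(col, "predictor", categories.get(col, "other"),
                           bounds=bounds.get(col))
            )
    return FeatureTable(df=df.reset_index(drop=True), meta=meta)


@pytest.fixture
def linear_table():
    """Noiseless k = 2*x1 + 5 over two groups."""
    rng = np.random.default_rng(7)
    x1 = rng.uniform(0, 10, 60)
    x2 = rng.uniform(0, 1, 60)
    df = pd.DataFrame(
        {
            "state": np.repeat(["A", "B"], 30),
            "x1": x1,
            "x2": x2,
            "k": 2 * x1 + 5,
        }
    )
    return make_table(df)


@pytest.fixture
def friedman_table():
    """The classic strongly nonlinear benchmark surface, rescaled to [0,100]."""
    rng = np.random.default_rng(11)
    n = 300
    X = rng.uniform(0, 1, (n, 5))
    y = (
        10 * np.sin(np.pi * X[:, 0] * X[:, 1])
        + 20 * (X[:, 2] - 0.5) ** 2
        + 10 * X[:, 3]
        + 5 * X[:, 4]
        + rng.normal(0, 1, n)
    )
    df = pd.DataFrame(X, columns=[f"x{i+1}" for i in range(5)])
    df["state"] = np.repeat([f"S{i}" for i in range(10)], n // 10)
    df["k"] = y
    return make_table(df)


@pytest.fixture
def grouped_normal_table():
    """k = 0.1*poverty + 8 with poverty ~ per-group Normal; 5 groups x 30."""
    rng = np.random.default_rng(3)
    frames = []
    for g in range(5):
        mu, sd = 10 + 3 * g, 2.0 + 0.3 * g
        pov = rng.normal(mu, sd, 30)
        frames.append(
            pd.DataFrame({"state": f"G{g}", "poverty": pov, "k": 0.1 * pov + 8})
        )
    df = pd.concat(frames, ignore_index=True)
    return make_table(df, categories={"poverty": "economic"})
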