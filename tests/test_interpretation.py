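import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from scenlearn import models
from scenlearn.interpret import compute_pdp, default_grid, pdp_band, rank_variables
from scenlearn.models import ModelSpec
from tests.conftest import make_table


def brute_force_pdp(model, table, predictor, grid):
    """Independent oracle: clone each row, overwrite, predict, average."""
    out = []
    for v in grid:
        preds = []
        for _, row in table.df[model.columns].iterrows():
            r = row.copy()
            r[predictor] = v
            preds.append(model.predict(pd.DataFrame([r]))[0])
        out.append(np.mean(preds))
    return np.array(out)


@pytest.fixture(scope="module")
def additive_table():
    df = pd.DataFrame(
        {
            "state": "A",
            "x1": [0.0, 1.0, 2.0, 5.0, 7.0, 9.0],
            "x2": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
        }
    )
    df["k"] = df.x1 + df.x2
    return make_table(df)


class TestComputePDP:
    def test_additive_closed_form(self, additive_table):
        m = models.fit(ModelSpec.make("glm"), additive_table)
        res = compute_pdp(m, additive_table, "x1", grid=[5.0])
        # pdp(x1=5) = 5 + mean(x2) = 5 + 1 = 6
        assert res.effect[0] == pytest.approx(6.0, abs=1e-8)

    def test_single_row_background_identity(self, additive_table):
        one = additive_table.with_df(additive_table.df.iloc[[2]])
        m = models.fit(ModelSpec.make("glm"), additive_table)
        v = 4.5
        res = compute_pdp(m, one, "x1", grid=[v])
        row = one.df[m.columns].copy()
        row["x1"] = v
        assert res.effect[0] == pytest.approx(m.predict(row)[0], abs=1e-12)

    @pytest.mark.parametrize("family", ["glm", "gam", "random_forest", "gbm"])
    def test_matches_brute_force_oracle(self, family, friedman_table):
        small = friedman_table.with_df(friedman_table.df.iloc[:50])
        spec = ModelSpec.make(family, **(
            {"n_estimators": 50} if family in ("random_forest", "gbm") else {}))
        m = models.fit(spec, small)
        grid = default_grid(small, "x1", 10)
        res = compute_pdp(m, small, "x1", grid)
        oracle = brute_force_pdp(m, small, "x1", grid)
        np.testing.assert_allclose(res.effect, oracle, atol=1e-10)

    def test_ignored_predictor_gives_flat_pdp(self, additive_table):
        df = additive_table.df.copy()
        rng = np.random.default_rng(0)
        df["irrelevant"] = rng.normal(size=len(df))
        t = make_table(df)
        m = models.fit(ModelSpec.make("glm"), additive_table)  # never saw 'irrelevant'

        # model that structurally ignores x2: zero coefficient via lasso on x1-only truth
        m2 = models.fit(ModelSpec.make("glm"), t.with_df(
            t.df.assign(k=t.df.x1 * 2)))
        res = compute_pdp(m2, t, "irrelevant", grid=np.linspace(-2, 2, 7))
        assert res.effect.max() - res.effect.min() < 1e-10

    def test_invariant_to_background_row_permutation(self, friedman_table):
        m = models.fit(ModelSpec.make("gbm", n_estimators=50), friedman_table)
        grid = default_grid(friedman_table, "x2", 8)
        a = compute_pdp(m, friedman_table, "x2", grid).effect
        perm = friedman_table.with_df(
            friedman_table.df.sample(frac=1, random_state=1))
        b = compute_pdp(m, perm, "x2", grid).effect
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_empty_grid_rejected(self, additive_table):
        m = models.fit(ModelSpec.make("glm"), additive_table)
        with pytest.raises(ValueError, match="empty grid"):
            compute_pdp(m, additive_table, "x1", grid=[])

    def test_extrapolating_grid_flagged(self, additive_table):
        m = models.fit(ModelSpec.make("glm"), additive_table)
        with pytest.warns(UserWarning, match="extrapolation"):
            compute_pdp(m, additive_table, "x1", grid=[-5.0, 20.0])

    def test_monotone_effect_recovered(self, grouped_normal_table):
        # poverty has a known positive effect on the outcome
        m = models.fit(ModelSpec.make("gbm", n_estimators=150), grouped_normal_table)
        x = grouped_normal_table.df["poverty"]
        grid = np.linspace(x.quantile(0.25), x.quantile(0.75), 15)
        res = compute_pdp(m, grouped_normal_table, "poverty", grid)
        rho, _ = spearmanr(grid, res.effect)
        assert rho > 0.9


class TestBands:
    def test_constant_model_zero_width(self, additive_table):
        t = additive_table.with_df(additive_table.df.assign(k=4.0))
        m = models.fit(ModelSpec.make("glm"), t)
        res = pdp_band(m, t, "x1", grid=[1.0, 2.0, 5.0], n_boot=50)
        np.testing.assert_allclose(res.upper - res.lower, 0.0, atol=1e-10)

    def test_single_bootstrap_degenerates_to_estimate(self, additive_table):
        m = models.fit(ModelSpec.make("glm"), additive_table)
        res = pdp_band(m, additive_table, "x1", grid=[1.0, 5.0], n_boot=1)
        np.testing.assert_array_equal(res.lower, res.effect)
        np.testing.assert_array_equal(res.upper, res.effect)

    def test_band_brackets_effect(self, friedman_table):
        m = models.fit(ModelSpec.make("gbm", n_estimators=50), friedman_table)
        res = pdp_band(m, friedman_table, "x4", n_boot=100, seed=3)
        assert (res.lower <= res.effect + 1e-12).all()
        assert (res.upper >= res.effect - 1e-12).all()

    def test_posterior_band_matches_percentiles_of_draws(self, friedman_table):
        small = friedman_table.with_df(friedman_table.df.iloc[:60])
        m = models.fit(
            ModelSpec.make("bart", n_trees=20, n_burn=50, n_draws=120), small)
        grid = default_grid(small, "x1", 5)
        res = pdp_band(m, small, "x1", grid)
        assert res.band_source == "posterior"
        # oracle: recompute draw-wise PDP from the stored posterior draws
        X = small.df[m.columns]
        per_draw = np.stack(
            [m.predict_draws(X.assign(x1=v)).mean(axis=1) for v in grid], axis=1
        )
        np.testing.assert_allclose(res.lower, np.quantile(per_draw, 0.025, axis=0),
                                   atol=1e-10)
        np.testing.assert_allclose(res.upper, np.quantile(per_draw, 0.975, axis=0),
                                   atol=1e-10)


class TestRanking:
    def test_single_driver_ranked_first(self, linear_table):
        m = models.fit(ModelSpec.make("gbm", n_estimators=80), linear_table)
        ranking = rank_variables(m, linear_table)
        assert ranking.index[0] == "x1"
        assert ranking.sum() == pytest.approx(1.0)
        assert (ranking.values[:-1] >= ranking.values[1:]).all()

    def test_all_noise_predictors_near_uniform(self):
        rng = np.random.default_rng(12)
        n = 500
        df = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(4)})
        df["state"] = "A"
        df["k"] = rng.normal(10, 1, n)
        t = make_table(df)
        m = models.fit(ModelSpec.make("random_forest", n_estimators=100), t)
        ranking = rank_variables(m, t)
        assert ranking.max() - ranking.min() < 0.15

    def test_rerun_same_seed_identical(self, friedman_table):
        m = models.fit(ModelSpec.make("gbm", n_estimators=50, seed=5), friedman_table)
        a = rank_variables(m, friedman_table, seed=2)
        b = rank_variables(m, friedman_table, seed=2)
        pd.testing.assert_series_equal(a, b)
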