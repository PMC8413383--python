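import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scenlearn import models
from scenlearn.models import ModelSpec
from scenlearn.scenario import (
    DistributionError,
    ScenarioSpec,
    adjudicate,
    default_hypotheses,
    fit_distribution,
    fit_group_distributions,
    perturb,
    run_scenario,
    select_family,
)
from tests.conftest import make_table


class TestMethodOfMoments:
    def test_normal_population_moments_hand_check(self):
        fit = fit_distribution([1, 2, 3] * 3, "normal")
        assert fit.params["mu"] == pytest.approx(2.0, abs=1e-12)
        assert fit.params["sigma"] ** 2 == pytest.approx(2 / 3, abs=1e-12)

    def test_exponential_rate_from_mean(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(4.0, 200)
        x = x * 4.0 / x.mean()  # force sample mean exactly 4
        fit = fit_distribution(x, "exponential")
        assert fit.params["rate"] == pytest.approx(0.25, abs=1e-12)

    def test_gamma_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(shape=3.0, scale=2.0, size=10_000)
        fit = fit_distribution(x, "gamma")
        assert 2.7 <= fit.params["shape"] <= 3.3
        assert 1.8 <= fit.params["scale"] <= 2.2

    @pytest.mark.parametrize("family", ["normal", "lognormal", "gamma", "uniform"])
    def test_two_parameter_families_match_both_moments(self, family):
        rng = np.random.default_rng(1)
        x = rng.gamma(5, 2, 500)
        fit = fit_distribution(x, family)
        assert fit.mean == pytest.approx(x.mean(), abs=1e-10)
        assert fit.sd**2 == pytest.approx(x.var(ddof=0), abs=1e-8)

    def test_support_violation_skips_family(self):
        with pytest.raises(DistributionError, match="positive support"):
            fit_distribution([-1.0, 2.0] * 5, "lognormal")

    def test_small_sample_rejected(self):
        with pytest.raises(DistributionError, match=">= 8"):
            fit_distribution([1, 2, 3], "normal")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_moment_matching_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(1.0, 0.4, 100)
        for fam in ("normal", "lognormal", "gamma", "uniform"):
            fit = fit_distribution(x, fam)
            assert fit.mean == pytest.approx(float(x.mean()), rel=1e-9)
            assert fit.sd == pytest.approx(float(x.std(ddof=0)), rel=1e-7)


class TestFamilySelection:
    def test_normal_sample_selects_normal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 5000)
        fit = select_family(x, ("normal", "uniform"))
        assert fit.family == "normal"

    def test_uniform_sample_selects_uniform(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 5000)
        fit = select_family(x, ("normal", "uniform"))
        assert fit.family == "uniform"

    def test_single_feasible_candidate_wins_regardless(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 200)  # has negatives: gamma/lognormal infeasible
        fit = select_family(x, ("lognormal", "gamma", "normal"))
        assert fit.family == "normal"

    def test_no_feasible_candidate_names_variable(self):
        with pytest.raises(DistributionError, match="povertyX"):
            select_family(np.array([-1.0, 1.0] * 10), ("gamma",), variable="povertyX")


class TestPerturb:
    def test_normal_location_shift(self):
        fit = fit_distribution(np.random.default_rng(0).normal(10, 2, 500), "normal")
        up = perturb(fit, +1.0)
        assert up.mean == pytest.approx(fit.mean + fit.sd, abs=1e-10)
        assert up.sd == pytest.approx(fit.sd, abs=1e-10)

    def test_zero_shift_is_identity(self):
        fit = fit_distribution(np.random.default_rng(1).gamma(4, 1, 500), "gamma")
        same = perturb(fit, 0.0)
        assert same.params == pytest.approx(fit.params)

    def test_gamma_reparameterized_hand_check(self):
        # gamma with mean 6, SD 2 shifted to mean 4, SD 2 -> shape 4, scale 1
        rng = np.random.default_rng(2)
        x = rng.gamma(9, 2 / 3, 20_000)
        x = (x - x.mean()) / x.std(ddof=0) * 2.0 + 6.0  # exact sample moments
        fit = fit_distribution(x, "gamma")
        down = perturb(fit, -1.0)
        assert down.params["shape"] == pytest.approx(4.0, abs=1e-8)
        assert down.params["scale"] == pytest.approx(1.0, abs=1e-8)

    def test_shift_out_of_support_advises_normal_fallback(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(1.2, 0.5, 500)  # mean < sd: a -2 sigma shift goes negative
        fit = fit_distribution(x, "gamma")
        with pytest.raises(DistributionError, match="normal"):
            perturb(fit, -2.0)


class TestRunScenario:
    def _model_and_fits(self, table):
        model = models.fit(ModelSpec.make("glm"), table)
        # the closed forms below assume the normal family (location shift)
        fits = fit_group_distributions(table, ["poverty"], candidates=("normal",))
        return model, fits

    def test_zero_shift_gives_exact_zero_delta(self, grouped_normal_table):
        model, fits = self._model_and_fits(grouped_normal_table)
        spec = ScenarioSpec.make("H0", {"poverty": 0.0}, "increase", n_draws=200)
        res = run_scenario(model, grouped_normal_table, spec, fits, seed=1)
        assert (res.per_group["delta_k"] == 0.0).all()

    def test_linear_model_closed_form_and_antisymmetry(self, grouped_normal_table):
        # k = 0.1*poverty + 8 exactly, so +1 sigma shifts K by 0.1*sigma_g
        model, fits = self._model_and_fits(grouped_normal_table)
        up = ScenarioSpec.make("H+", {"poverty": +1.0}, "increase", n_draws=100)
        dn = ScenarioSpec.make("H-", {"poverty": -1.0}, "decrease", n_draws=100)
        res_up = run_scenario(model, grouped_normal_table, up, fits, seed=5)
        res_dn = run_scenario(model, grouped_normal_table, dn, fits, seed=5)
        for _, row in res_up.per_group.iterrows():
            sigma = fits[(row["group"], "poverty")].sd
            assert row["delta_k"] == pytest.approx(0.1 * sigma, abs=1e-8)
        merged = res_up.per_group.merge(res_dn.per_group, on="group")
        np.testing.assert_allclose(
            merged["delta_k_x"], -merged["delta_k_y"], atol=1e-8)

    def test_delta_kappa_identity(self, grouped_normal_table):
        model, fits = self._model_and_fits(grouped_normal_table)
        spec = ScenarioSpec.make("H1", {"poverty": 1.0}, "increase", n_draws=150)
        res = run_scenario(model, grouped_normal_table, spec, fits, seed=2)
        for _, row in res.per_group.iterrows():
            assert row["delta_kappa"] * row["k_base"] / 100 == pytest.approx(
                row["delta_k"], abs=1e-12)

    def test_hand_arithmetic_delta_kappa(self):
        # K_base 13.4 -> K_scenario 13.0 gives dK -0.4, dkappa about -2.985%
        dk = 13.0 - 13.4
        assert dk / 13.4 * 100 == pytest.approx(-2.985, abs=1e-3)

    def test_common_random_numbers_make_reruns_identical(self, grouped_normal_table):
        model, fits = self._model_and_fits(grouped_normal_table)
        spec = ScenarioSpec.make("H1", {"poverty": 1.0}, "increase", n_draws=100)
        a = run_scenario(model, grouped_normal_table, spec, fits, seed=9).per_group
        b = run_scenario(model, grouped_normal_table, spec, fits, seed=9).per_group
        pd.testing.assert_frame_equal(a, b)

    def test_substitution_locality(self, grouped_normal_table):
        """Non-perturbed columns of the scenario rows are bit-identical."""
        df = grouped_normal_table.df.copy()
        rng = np.random.default_rng(4)
        df["untouched"] = rng.normal(size=len(df))
        t = make_table(df, categories={"poverty": "economic"})
        captured = {}

        model = models.fit(ModelSpec.make("glm"), t)
        orig_predict = model.predict

        def spy(X):
            captured.setdefault("blocks", []).append(np.asarray(X["untouched"]))
            return orig_predict(X)

        model.predict = spy
        fits = fit_group_distributions(t, ["poverty"])
        spec = ScenarioSpec.make("H1", {"poverty": 1.0}, "increase", n_draws=13)
        run_scenario(model, t, spec, fits, seed=0)
        base_blocks = captured["blocks"][0::2]
        scen_blocks = captured["blocks"][1::2]
        for b, s in zip(base_blocks, scen_blocks):
            np.testing.assert_array_equal(b, s)

    def test_out_of_support_shift_falls_back_to_normal(self):
        # exponential has SD = mean, so a -1 sigma shift lands on mean 0;
        # the engine must fall back to a moment-matched normal, not crash
        rng = np.random.default_rng(8)
        frames = []
        for g in range(2):
            frames.append(pd.DataFrame({
                "state": f"G{g}", "v": rng.exponential(3.0, 60)}))
        df = pd.concat(frames, ignore_index=True)
        df["k"] = 10 + 0.5 * df.v
        t = make_table(df, categories={"v": "economic"})
        model = models.fit(ModelSpec.make("glm"), t)
        fits = fit_group_distributions(t, ["v"], candidates=("exponential",))
        spec = ScenarioSpec.make("H-", {"v": -1.0}, "decrease", n_draws=100)
        res = run_scenario(model, t, spec, fits, seed=0)
        assert (res.per_group["delta_k"] < 0).all()

    def test_bounded_variable_draws_clipped(self):
        rng = np.random.default_rng(5)
        frames = []
        for g in range(3):
            v = np.clip(rng.normal(95, 4, 40), 0, 100)  # near the upper bound
            frames.append(pd.DataFrame({"state": f"G{g}", "pct": v, "k": v / 10}))
        df = pd.concat(frames, ignore_index=True)
        t = make_table(df, categories={"pct": "economic"}, bounds={"pct": (0, 100)})
        model = models.fit(ModelSpec.make("glm"), t)
        fits = fit_group_distributions(t, ["pct"])
        spec = ScenarioSpec.make("H1", {"pct": 1.0}, "increase", n_draws=400)
        res = run_scenario(model, t, spec, fits, seed=0)
        assert res.clip_rate > 0


class TestAdjudicate:
    def _result(self, deltas, expected):
        model_table_rows = pd.DataFrame(
            {
                "group": [f"G{i}" for i in range(len(deltas))],
                "k_base": 13.0,
                "k_scenario": 13.0 + np.array(deltas),
                "delta_k": deltas,
                "delta_kappa": np.array(deltas) / 13 * 100,
                "supported": [
                    d > 0 if expected == "increase" else d < 0 for d in deltas
                ],
            }
        )
        from scenlearn.scenario import ScenarioResult

        mean_dk = float(np.mean(deltas))
        return ScenarioResult(
            hypothesis_id="H1",
            expected=expected,
            per_group=model_table_rows,
            national_mean_delta_k=mean_dk,
            classification="worst-case" if mean_dk > 0
            else ("best-case" if mean_dk < 0 else "neutral"),
        )

    def test_all_positive_expected_increase_worst_case(self):
        res = self._result([0.2, 0.4, 0.1], "increase")
        v = adjudicate(res, ScenarioSpec.make("H1", {"x": 1.0}, "increase"))
        assert v.classification == "worst-case"
        assert v.nationally_supported
        assert v.nonconforming_groups == []

    def test_negative_mean_is_best_case(self):
        res = self._result([-0.3, -0.1, 0.05], "decrease")
        v = adjudicate(res, ScenarioSpec.make("H2", {"x": -1.0}, "decrease"))
        assert v.classification == "best-case"
        assert v.nationally_supported

    def test_mixed_signs_list_nonconforming_groups(self):
        res = self._result([0.2, -0.4, 0.1], "increase")
        v = adjudicate(res, ScenarioSpec.make("H1", {"x": 1.0}, "increase"))
        assert v.nonconforming_groups == ["G1"]
        assert set(v.supported_groups) == {"G0", "G2"}


class TestDefaultHypotheses:
    def test_battery_covers_ten_ids(self):
        from scenlearn import synthetic

        table, _ = synthetic.generate(
            synthetic.default_config(n_groups=4, communities_per_group=(10, 12)),
            seed=0,
        )
        specs = default_hypotheses(table)
        assert [s.hypothesis_id for s in specs] == [f"H{i}" for i in range(1, 11)]
        h1 = specs[0]
        dirs = h1.direction_map
        assert dirs["poverty_rate"] == +1 and dirs["median_income_k"] == -1
        assert h1.expected == "increase"
        # mirrored pairs point in opposite directions
        h2 = specs[1]
        assert {v: -s for v, s in h2.direction_map.items()} == dirs
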