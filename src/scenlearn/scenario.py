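"""Scenario-based sensitivity analysis over grouped predictor distributions.

For every group (state) and every perturbable predictor, a parametric
distribution is chosen from a candidate set by chi-squared goodness of fit,
with parameters estimated by the method of moments. A scenario shifts the
mean of each listed predictor's distribution by +/- one (group-level)
standard deviation while holding the SD fixed; base-case values (BV) and
scenario values are sampled through common random numbers (shared uniforms
pushed through each distribution's inverse CDF) so the contrast isolates
the shift. The model re-predicts the response on the substituted rows and

    Delta K     = K_scenario - K_base,
    Delta kappa = Delta K / K_base * 100%,

are computed per group. Nationally, the scenario is classified worst-case
when the mean Delta K across groups is positive and best-case when it is
negative; per-group hypothesis verdicts compare the sign of Delta K with
the hypothesized direction.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureTable
from .models import FittedModel

logger = logging.getLogger(__name__)

CANDIDATE_FAMILIES = ("normal", "lognormal", "gamma", "exponential", "uniform")


class DistributionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# method-of-moments fitting
# ---------------------------------------------------------------------------

def _mom_params(family: str, mean: float, var: float) -> dict[str, float]:
    """Solve the family's moment equations for (mean, variance)."""
    if family == "normal":
        return {"mu": mean, "sigma": math.sqrt(var)}
    if family == "lognormal":
        if mean <= 0:
            raise DistributionError("lognormal requires positive mean")
        s2 = math.log(1.0 + var / mean**2)
        return {"mu": math.log(mean) - s2 / 2.0, "sigma": math.sqrt(s2)}
    if family == "gamma":
        if mean <= 0 or var <= 0:
            raise DistributionError("gamma requires positive mean and variance")
        return {"shape": mean**2 / var, "scale": var / mean}
    if family == "exponential":
        if mean <= 0:
            raise DistributionError("exponential requires positive mean")
        return {"rate": 1.0 / mean}
    if family == "uniform":
        h = math.sqrt(3.0 * var)
        return {"lo": mean - h, "hi": mean + h}
    raise DistributionError(f"unknown family {family!r}")


def _frozen(family: str, params: dict[str, float]):
    if family == "normal":
        return stats.norm(params["mu"], params["sigma"])
    if family == "lognormal":
        return stats.lognorm(s=params["sigma"], scale=math.exp(params["mu"]))
    if family == "gamma":
        return stats.gamma(a=params["shape"], scale=params["scale"])
    if family == "exponential":
        return stats.expon(scale=1.0 / params["rate"])
    if family == "uniform":
        return stats.uniform(loc=params["lo"], scale=params["hi"] - params["lo"])
    raise DistributionError(f"unknown family {family!r}")


def _support_ok(family: str, values: np.ndarray) -> bool:
    if family in ("lognormal", "gamma", "exponential"):
        return bool(np.all(values > 0))
    return True


@dataclass
class DistributionFit:
    """A moment-matched parametric fit for one (group, variable) sample."""

    group: str
    variable: str
    family: str
    params: dict[str, float]
    gof_statistic: float
    gof_pvalue: float
    n: int

    @property
    def dist(self):
        return _frozen(self.family, self.params)

    @property
    def mean(self) -> float:
        return float(self.dist.mean())

    @property
    def sd(self) -> float:
        return float(self.dist.std())

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return self.dist.ppf(u)


def _chi2_gof(values: np.ndarray, dist, n_params: int, n_bins: int = 10):
    """Chi-squared GOF with equiprobable bins (expected count >= 5)."""
    n = len(values)
    k = min(n_bins, max(n // 5, 2))
    edges = dist.ppf(np.linspace(0, 1, k + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    obs, _ = np.histogram(values, bins=edges)
    exp = np.full(k, n / k)
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    dof = max(k - 1 - n_params, 1)
    return statistic, float(stats.chi2.sf(statistic, dof))


_N_PARAMS = {"normal": 2, "lognormal": 2, "gamma": 2, "exponential": 1, "uniform": 2}


def fit_distribution(
    values, family: str, group: str = "", variable: str = ""
) -> DistributionFit:
    """Method-of-moments fit of one candidate family to a sample.

    Population moments (divide by n) are used. Raises
    :class:`DistributionError` when the sample leaves the family's support
    (e.g. non-positive values for lognormal).
    """
    values = np.asarray(values, float)
    if len(values) < 8:
        raise DistributionError(f"need >= 8 observations, got {len(values)}")
    if not _support_ok(family, values):
        raise DistributionError(
            f"{family} requires positive support; sample for "
            f"({group!r}, {variable!r}) has non-positive values"
        )
    mean = float(values.mean())
    var = float(values.var(ddof=0))
    if var == 0:
        raise DistributionError("zero-variance sample cannot be fitted")
    params = _mom_params(family, mean, var)
    statistic, pvalue = _chi2_gof(values, _frozen(family, params), _N_PARAMS[family])
    return DistributionFit(
        group=group,
        variable=variable,
        family=family,
        params=params,
        gof_statistic=statistic,
        gof_pvalue=pvalue,
        n=len(values),
    )


def select_family(
    values, candidates=CANDIDATE_FAMILIES, group: str = "", variable: str = ""
) -> DistributionFit:
    """Best feasible candidate by smallest chi-squared statistic.

    Ties are broken by candidate order (logged); infeasible candidates
    (support violations) are skipped with the reason recorded.
    """
    fits, skipped = [], []
    for fam in candidates:
        try:
            fits.append(fit_distribution(values, fam, group=group, variable=variable))
        except DistributionError as exc:
            skipped.append((fam, str(exc)))
    if not fits:
        raise DistributionError(
            f"no feasible candidate family for ({group!r}, {variable!r}): {skipped}"
        )
    best = min(fits, key=lambda f: f.gof_statistic)
    ties = [f for f in fits if f is not best and f.gof_statistic == best.gof_statistic]
    if ties:
        logger.info(
            "GOF tie for (%s, %s): kept %s by candidate order",
            group,
            variable,
            best.family,
        )
    return best


def perturb(fit: DistributionFit, shift: float) -> DistributionFit:
    """Shift the fitted mean by ``shift`` standard deviations, same SD.

    The family's parameters are re-solved from the new (mean, variance)
    pair. The exponential family has a single parameter, so only the mean
    is matched (its SD necessarily moves with the mean). If the shifted
    mean leaves the family's support a :class:`DistributionError` is
    raised with guidance to fall back to the normal family.
    """
    mean, sd = fit.mean, fit.sd
    new_mean = mean + shift * sd
    if fit.family in ("lognormal", "gamma", "exponential") and new_mean <= 0:
        raise DistributionError(
            f"shifted mean {new_mean:.4g} leaves the {fit.family} support for "
            f"({fit.group!r}, {fit.variable!r}); refit with the normal family"
        )
    params = _mom_params(fit.family, new_mean, sd**2)
    return DistributionFit(
        group=fit.group,
        variable=fit.variable,
        family=fit.family,
        params=params,
        gof_statistic=fit.gof_statistic,
        gof_pvalue=fit.gof_pvalue,
        n=fit.n,
    )


def fit_group_distributions(
    table: FeatureTable,
    variables,
    candidates=CANDIDATE_FAMILIES,
    min_group_size: int = 8,
) -> dict[tuple[str, str], DistributionFit]:
    """Select and fit a family for every (group, variable) pair."""
    fits: dict[tuple[str, str], DistributionFit] = {}
    for group, sub in table.df.groupby(table.group_name, sort=True):
        if len(sub) < min_group_size:
            logger.warning(
                "group %s has %d rows (< %d); distributions not fitted",
                group,
                len(sub),
                min_group_size,
            )
            continue
        for var in variables:
            fits[(str(group), var)] = select_family(
                sub[var].to_numpy(float), candidates, group=str(group), variable=var
            )
    return fits


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One directional hypothesis: which variables shift, which way.

    ``directions`` maps predictor name -> shift in SD units (+1 or -1;
    joint scenarios list several variables). ``expected`` states the
    hypothesized effect on the response ('increase' or 'decrease').
    """

    hypothesis_id: str
    directions: tuple  # ((variable, shift), ...)
    expected: str
    n_draws: int = 1000

    def __post_init__(self):
        if self.expected not in ("increase", "decrease"):
            raise ValueError("expected must be 'increase' or 'decrease'")

    @property
    def variables(self) -> list[str]:
        return [v for v, _ in self.directions]

    @property
    def direction_map(self) -> dict[str, float]:
        return dict(self.directions)

    @staticmethod
    def make(hypothesis_id, directions: dict, expected, n_draws=1000) -> "ScenarioSpec":
        return ScenarioSpec(
            hypothesis_id=hypothesis_id,
            directions=tuple(directions.items()),
            expected=expected,
            n_draws=n_draws,
        )


@dataclass
class ScenarioResult:
    hypothesis_id: str
    expected: str
    per_group: pd.DataFrame  # group, k_base, k_scenario, delta_k, delta_kappa, supported
    national_mean_delta_k: float
    classification: str  # 'worst-case' | 'best-case' | 'neutral'
    clip_rate: float = 0.0
    skipped_groups: list = field(default_factory=list)

    @property
    def supported_groups(self) -> list[str]:
        return self.per_group.loc[self.per_group["supported"], "group"].tolist()

    @property
    def nonconforming_groups(self) -> list[str]:
        return self.per_group.loc[~self.per_group["supported"], "group"].tolist()

    def write_csv(self, path) -> None:
        out = self.per_group.copy()
        out.insert(0, "hypothesis", self.hypothesis_id)
        out.to_csv(path, index=False)


def _group_seed(master: int, group: str, hypothesis: str) -> int:
    h = zlib.crc32(f"{group}|{hypothesis}".encode())
    return int((master * 1_000_003 + h) % (2**31 - 1))


def run_scenario(
    model: FittedModel,
    table: FeatureTable,
    spec: ScenarioSpec,
    fits: dict[tuple[str, str], DistributionFit],
    seed: int = 0,
) -> ScenarioResult:
    """Predict the response under one perturbation scenario, per group.

    For each group, ``n_draws`` base values are sampled from the fitted
    unperturbed distributions and scenario values from the mean-shifted
    ones, using common random numbers. Each draw replaces the scenario
    variables in copies of the group's rows (all other columns untouched);
    K_base and K_scenario are the mean predictions over all substituted
    copies. Sampled values of bounded variables are clipped to their
    declared bounds, with the clip rate reported.
    """
    rows = []
    skipped = []
    clipped = total = 0
    shifted = {}
    for group in sorted(table.groups.astype(str).unique()):
        missing = [v for v in spec.variables if (group, v) not in fits]
        if missing:
            skipped.append(group)
            logger.warning("group %s skipped: no fit for %s", group, missing)
            continue
        sub = table.df[table.groups.astype(str) == group]
        if len(sub) == 0:
            skipped.append(group)
            continue
        rng = np.random.default_rng(_group_seed(seed, group, spec.hypothesis_id))
        n_rows = len(sub)
        base_block = pd.concat([sub[model.columns]] * spec.n_draws, ignore_index=True)
        scen_block = base_block.copy()
        for var, shift in spec.directions:
            fit = fits[(group, var)]
            try:
                pert = perturb(fit, shift)
            except DistributionError:
                # shifted mean left the family's support: fall back to a
                # normal with the same moments (base draws follow suit so
                # the common-random-number coupling stays consistent)
                logger.warning(
                    "(%s, %s): %s mean shift leaves support; normal fallback",
                    group,
                    var,
                    fit.family,
                )
                fit = DistributionFit(
                    group=group,
                    variable=var,
                    family="normal",
                    params={"mu": fit.mean, "sigma": fit.sd},
                    gof_statistic=fit.gof_statistic,
                    gof_pvalue=fit.gof_pvalue,
                    n=fit.n,
                )
                pert = perturb(fit, shift)
            shifted[(group, var)] = pert
            u = rng.uniform(size=spec.n_draws)
            bv = fit.ppf(u)
            sv = pert.ppf(u)
            meta = table.column_meta(var)
            if meta.bounds is not None:
                lo, hi = meta.bounds
                clipped += int(np.sum((bv < lo) | (bv > hi) | (sv < lo) | (sv > hi)))
                total += 2 * len(u)
                bv, sv = np.clip(bv, lo, hi), np.clip(sv, lo, hi)
            base_block[var] = np.repeat(bv, n_rows)
            scen_block[var] = np.repeat(sv, n_rows)
        k_base = float(model.predict(base_block).mean())
        k_scen = float(model.predict(scen_block).mean())
        dk = k_scen - k_base
        dkappa = dk / k_base * 100.0 if k_base != 0 else float("nan")
        sign_ok = dk > 0 if spec.expected == "increase" else dk < 0
        rows.append(
            {
                "group": group,
                "k_base": k_base,
                "k_scenario": k_scen,
                "delta_k": dk,
                "delta_kappa": dkappa,
                "supported": bool(sign_ok),
            }
        )
    if not rows:
        raise RuntimeError(f"scenario {spec.hypothesis_id}: no group could be evaluated")
    per_group = pd.DataFrame(rows)
    mean_dk = float(per_group["delta_k"].mean())
    if mean_dk > 0:
        classification = "worst-case"
    elif mean_dk < 0:
        classification = "best-case"
    else:
        classification = "neutral"
    clip_rate = clipped / total if total else 0.0
    if clip_rate > 0:
        logger.info(
            "scenario %s: clipped %.2f%% of sampled values to declared bounds",
            spec.hypothesis_id,
            100 * clip_rate,
        )
    return ScenarioResult(
        hypothesis_id=spec.hypothesis_id,
        expected=spec.expected,
        per_group=per_group,
        national_mean_delta_k=mean_dk,
        classification=classification,
        clip_rate=clip_rate,
        skipped_groups=skipped,
    )


@dataclass
class Verdict:
    hypothesis_id: str
    expected: str
    classification: str
    national_mean_delta_k: float
    nationally_supported: bool
    supported_groups: list[str]
    nonconforming_groups: list[str]


def adjudicate(result: ScenarioResult, spec: ScenarioSpec) -> Verdict:
    """Sign-based verdicts: per group and nationally.

    The hypothesis is nationally supported when the national mean Delta K
    has the hypothesized sign (worst-case for an expected increase,
    best-case for an expected decrease). Groups whose Delta K sign
    disagrees are listed as nonconforming.
    """
    expected_class = "worst-case" if spec.expected == "increase" else "best-case"
    return Verdict(
        hypothesis_id=spec.hypothesis_id,
        expected=spec.expected,
        classification=result.classification,
        national_mean_delta_k=result.national_mean_delta_k,
        nationally_supported=result.classification == expected_class,
        supported_groups=result.supported_groups,
        nonconforming_groups=result.nonconforming_groups,
    )


# ---------------------------------------------------------------------------
# default hypothesis battery
# ---------------------------------------------------------------------------

def default_hypotheses(
    table: FeatureTable,
    sign_map: dict[str, float] | None = None,
    n_draws: int = 1000,
) -> list[ScenarioSpec]:
    """The standard ten directional hypotheses over predictor categories.

    H1/H2 jointly perturb the economic variables (degradation/boom), H3/H4
    insurance availability, H5/H6 access to public insurance, H7/H8
    transport cost, H9/H10 housing vacancy. ``sign_map`` gives the within-
    scenario orientation of each economic variable under *degradation*
    (default: +1 for poverty- and unemployment-like variables, -1 for
    income-like ones, inferred from column names; pass explicitly for
    other naming schemes).
    """
    econ = table.predictors_in_category("economic")
    if sign_map is None:
        sign_map = {
            v: (-1.0 if "income" in v.lower() else +1.0) for v in econ
        }
    specs: list[ScenarioSpec] = []

    def add(hid, directions, expected):
        if directions:
            specs.append(ScenarioSpec.make(hid, directions, expected, n_draws))

    if econ:
        degradation = {v: sign_map.get(v, 1.0) for v in econ}
        boom = {v: -s for v, s in degradation.items()}
        add("H1", degradation, "increase")
        add("H2", boom, "decrease")
    # insurance_availability measures *lack* of insurance (share of families
    # with no health insurance); insurance_type measures *access* to public
    # insurance — hence the opposite expected signs for the two categories.
    for hid_dec, hid_inc, category, down_expect, up_expect in [
        ("H3", "H4", "insurance_availability", "decrease", "increase"),
        ("H5", "H6", "insurance_type", "increase", "decrease"),
        ("H7", "H8", "transport_cost", "decrease", "increase"),
        ("H9", "H10", "housing_vacancy", "decrease", "increase"),
    ]:
        for v in table.predictors_in_category(category):
            add(hid_dec, {v: -1.0}, down_expect)
            add(hid_inc, {v: +1.0}, up_expect)
    # keep canonical ordering H1..H10
    order = {f"H{i}": i for i in range(1, 11)}
    specs.sort(key=lambda s: order.get(s.hypothesis_id, 99))
    return specs
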