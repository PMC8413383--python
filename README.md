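# scenlearn

Scenario-based predictive analytics for grouped community health outcomes.

`scenlearn` is for epidemiologists and health-policy analysts who have a
table of communities — one row per metropolitan community, a continuous
outcome, predictors describing the built environment, and a grouping
column such as US state — and want to answer three questions with one
reproducible workflow:

1. **Which interpretable regression model predicts the outcome best?**
   A library of eight families (GLM, ridge, lasso, GAM, MARS variants,
   random forest, gradient boosting, and a Bayesian sum-of-trees
   ensemble) is compared by repeated randomized 80–20 holdout validation
   (default 30 repeats) on in- and out-of-sample R², RMSE and MAE,
   against a null model that predicts the training mean.
2. **What drives the predictions?** Variable-importance rankings
   (split-inclusion proportions for tree ensembles, permutation
   importance otherwise) and partial dependence plots with 95% bands,

   $$p_j(x_j) = \frac{1}{n}\sum_{i=1}^{n} \hat f(x_j,\, x_{-j,i}).$$

3. **What happens under plausible change?** For each group, parametric
   distributions of the perturbable predictors are chosen by chi-squared
   goodness of fit with method-of-moments estimation; a scenario shifts
   each distribution's mean by ±1 SD (SD held fixed), resamples with
   common random numbers, re-predicts, and reports per group

   $$\Delta K = K_{\text{scenario}} - K_{\text{base}},\qquad
     \Delta\kappa = \frac{\Delta K}{K_{\text{base}}}\times 100\%.$$

   A scenario is classified *worst-case* when the across-group mean
   $\Delta K$ is positive and *best-case* when negative; ten default
   directional hypotheses (H1–H10) cover economic degradation/boom,
   insurance availability, insurance type, transport cost and housing
   vacancy.

Correlated pre-clinical health variables can be reduced to principal
components before modelling (smallest number of components reaching a
configured explained-variance threshold, default 92%). A synthetic-data
module generates grouped studies with known ground truth so the whole
pipeline is testable without any external data.

## Worked example

```python
from scenlearn import CommunityOutcomeModel, ScenarioSpec, synthetic

table, truth = synthetic.generate(seed=1)          # ~1,350 communities, 50 states
res = CommunityOutcomeModel(table).fit(
    families=["glm", "gam", "gbm"], repeats=10, seed=1)
print(res.summary())

pdp = res.partial_dependence("poverty_rate", band=False)
print("PDP range:", round(pdp.effect.min(), 2), "->", round(pdp.effect.max(), 2))

out = res.run_scenario(ScenarioSpec.make(
    "H1",
    {"poverty_rate": +1.0, "unemployment_rate": +1.0, "median_income_k": -1.0},
    expected="increase", n_draws=300))
print("national mean dK:", round(out.national_mean_delta_k, 3),
      "->", out.classification)
```

Output:

```
Community outcome model selection (repeated 80-20 holdout)
==============================================================
rows: 1354   groups: 50   repeats: 10
selected model: gam
--------------------------------------------------------------
       r2_full_fit  rmse_in_mean  rmse_out_mean  mae_in_mean  mae_out_mean
model
glm         0.8992        0.4681         0.4775       0.3739        0.3815
gam         0.9133        0.4339         0.4697       0.3452        0.3741
gbm         0.9365        0.3500         0.5680       0.2811        0.4544
null           NaN        1.4785         1.4774       1.1832        1.1849
PDP range: 10.62 -> 15.2
national mean dK: 1.099 -> worst-case
```

(Groups with fewer than 8 communities are skipped by the distribution
fitter, with a logged warning.)

The GAM wins on out-of-sample RMSE (0.470, close to the generator's
noise SD of 0.45, versus 1.48 for the null model; the boosted ensemble
fits tighter in-sample but generalizes worse here). The partial effect of
poverty spans ~4.6 percentage points of the outcome across its observed
range, consistent with the generator's true coefficient of 0.20 per
point of poverty. Jointly degrading the economic variables by one
within-state SD raises the predicted share of adults reporting poor
mental health by ≈1.1 percentage points on average across states — a
worst-case scenario, as the data-generating process dictates.

The same workflow is scriptable from the shell:

```bash
scenlearn generate --out demo --seed 1 --n-groups 10 --communities 10 30
scenlearn select demo/communities.csv demo/columns.json --repeats 10
scenlearn run --synthetic --seed 1 --outdir run1   # full pipeline + report.md
```

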