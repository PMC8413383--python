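# Methods

`scenlearn` implements a multi-stage workflow for community-level health
outcomes: model selection over a library of interpretable regression
learners, model interpretation through variable importance and partial
dependence, and scenario-based sensitivity analysis of grouped predictor
distributions. This note documents the model, the defaults, the numerical
choices, and the limits of what the synthetic studies demonstrate.

## The modelling problem

Each row of a feature table is one metropolitan community. The response
`K` is the percentage of adults (>18 y) reporting poor mental health for
more than 14 of the past 30 days, constrained to [0, 100]. Predictors are
tagged by category: economic conditions (poverty incidence, unemployment,
household income), insurance availability (share of families without
health insurance), insurance type (access to public insurance), transport
cost (% of income), housing vacancy, behavioral controls, and pre-clinical
health variables. A group key (US state) defines the grouping over which
distributions are fitted and scenario results aggregated.

## Pre-processing: PCA of the pre-clinical block

Pre-clinical health variables are typically strongly correlated. The
`preclinical`-tagged columns are standardized (zero mean, unit variance —
a deliberate choice, since the variables carry heterogeneous units) and
replaced by the smallest number of principal components whose cumulative
explained variance reaches a threshold (default 0.92). Loadings, explained
ratios, and the standardization constants are recorded so the reduction is
reproducible and invertible up to the retained subspace. With fewer than
two pre-clinical columns the step is a no-op.

## The model library

Eight families sit behind one fit/predict contract (`scenlearn.models`):

| family | backend | defaults |
|---|---|---|
| glm | statsmodels OLS (Gaussian) | — |
| ridge | scikit-learn `Ridge` | `alpha=1.0` |
| lasso | scikit-learn `Lasso` | `alpha=0.01` |
| gam | B-spline basis (6 knots, cubic) + ridge | penalty by efficient LOO (GCV-style) over `1e-4..1e6` |
| mars | in-repo hinge-basis search | degree 1/2/3 variants, pruning penalty 2, 7 candidate knots/variable |
| random_forest | scikit-learn | 200 trees, `max_features=1/3`, `min_samples_leaf=2` |
| gbm | scikit-learn | 200 trees, learning rate 0.05, depth 3, subsample 0.8 |
| bart | in-repo sum-of-trees sampler | 50 trees, 200 burn-in, 500 kept draws |

The GAM's smoothing penalty is a single ridge penalty on the spline
coefficients chosen by the closed-form leave-one-out criterion; predictors
with too few distinct values for a spline basis enter linearly, and spline
evaluation clamps to the training range.

The MARS implementation runs the classical forward pass (mirrored hinge
pairs `max(0, x-t)`/`max(0, t-x)` on quantile knots, products up to the
interaction degree) followed by backward pruning under
`GCV = RSS/n / (1 - C/n)^2` with `C = #coefficients + penalty * #knots`.
It is a compact implementation: knot candidates are limited to 7 interior
quantiles per variable and the forward pass stops at ~21 terms, which
trades some fidelity on very wiggly surfaces for predictable runtime.

The Bayesian tree ensemble models the (internally rescaled) response as a
sum of `m` trees plus `N(0, sigma^2)` noise. Priors follow the standard
regularizing choices: split probability `0.95 (1+depth)^-2`, leaf values
`N(0, (0.5/(2 sqrt(m)))^2)`, and a scaled-inverse-chi-squared prior on
`sigma^2` with 3 degrees of freedom calibrated so its 0.9 quantile sits at
the sample SD. Structure moves are Metropolis-Hastings GROW/PRUNE steps
with leaf values integrated out; leaf values and `sigma^2` are then drawn
conjugately. A zero-variance response is handled as a degenerate constant
model. Point predictions are posterior means; credible bands use the
per-draw predictions; variable importance is the inclusion proportion of
splitting rules across kept forests. The sampler is deliberately minimal
(no CHANGE/SWAP moves, uniform variable/cut proposals); it is adequate as
a library member but is not tuned for large `p`.

Importance scores are always non-negative and normalized to sum to one.
Families without a native score fall back to permutation importance
(10 permutations per column, seeded), with a warning.

## Model selection

`make_splits(n, repeats, seed)` draws `repeats` (default 30) independent
random splits with `round(0.8 n)` training rows (at least one test row).
Coverage — every row trains at least once — is verified after drawing and
the plan re-drawn in the (negligible-probability) failure case; when
coverage is arithmetically impossible (e.g. a single repeat) the check is
skipped with a warning. Each family is scored in- and out-of-sample with
R², RMSE and MAE; a null model predicting the training mean anchors the
table, and its R² is reported as not applicable. The comparison table also
carries each family's in-sample R² from a full-data refit, which is the
single goodness-of-fit column conventionally quoted next to the holdout
metrics. Selection minimizes mean out-of-sample RMSE with ties broken by
out-of-sample MAE, then in-sample RMSE, then registry order (logged):
holdout error is the generalization-focused criterion, with in-sample fit
only as a tie-breaker. A zero-variance response makes R² undefined; the
scorer returns NaN for R² (with a warning) and still reports RMSE/MAE.

## Interpretation

The partial effect of predictor `x_j` at value `v` is
`p_j(v) = (1/n) Σ_i f(v, x_{-j,i})`: every background row is cloned, its
j-th column overwritten, and predictions averaged. The default grid is 25
equally spaced quantiles between q0.01 and q0.99; grids beyond the
observed range are allowed but flagged as extrapolation. Bands (default
95%) come from posterior draws when the model provides them (draw-wise
PDPs, percentile interval), otherwise from a nonparametric bootstrap of
the background rows (default B=200). These bands describe uncertainty of
the averaged effect, not prediction intervals. A single bootstrap
resample carries no spread, so B=1 returns a degenerate band at the point
estimate.

## Scenario engine

For each group and perturbable variable, a parametric family is selected
from {normal, lognormal, gamma, exponential, uniform} — a fixed candidate
set chosen to cover symmetric, right-skewed and bounded shapes of
percentage-type variables — by the smallest chi-squared statistic over
equiprobable bins (10 bins, reduced so expected counts stay ≥ 5; degrees
of freedom = bins − 1 − #parameters). Parameters are estimated by the
method of moments using population moments (divide by n). The exponential
family has one parameter, so only the mean is matched, and a mean shift
necessarily moves its SD too.

A scenario shifts each listed variable's mean by ±1 group-level SD while
holding the SD fixed, re-solving the family's parameters from the new
(mean, variance) pair. Base-case values are *sampled* from the unperturbed
fit (not the observed values), and base/scenario draws share the same
uniforms through the inverse CDF (common random numbers) — a variance-
reduction choice that makes a zero shift produce exactly zero change and
isolates the mean shift from Monte-Carlo noise. Joint scenarios (the
economic triple) perturb all listed variables simultaneously as
independent marginals; preserving their correlation is out of scope.
Sampled values of bounded variables are clipped to their declared bounds
and the clip rate logged. Per group, each of the `n_draws` (default 1000)
sampled values is substituted into copies of all of the group's rows,
leaving every other column untouched; `K_base` and `K_scenario` are mean
predictions over the substituted copies, and

    ΔK = K_scenario − K_base,    Δκ = ΔK / K_base × 100%.

The national classification is worst-case if the across-group mean ΔK is
positive, best-case if negative. Hypothesis verdicts are sign-based only
(no formal test is attached): a group supports a hypothesis when its ΔK
sign matches the expected direction, and nonconforming groups are listed.
Group-level seeds fan out deterministically from the master seed per
(group, scenario), so results are reproducible and scenario sets can be
extended without disturbing earlier draws.

The default battery of ten hypotheses mirrors the built-environment
categories: H1/H2 jointly degrade/boom the economic variables (poverty
+1σ, unemployment +1σ, income −1σ under degradation; the sign map is
configurable since "income" orientation depends on the variable's
definition), H3/H4 move insurance unavailability down/up, H5/H6 move
public-insurance access down/up, H7/H8 transport cost, H9/H10 housing
vacancy.

## Synthetic studies

The generator draws ~50 groups of 5–50 communities. Each predictor has a
per-group marginal (family plus mean/SD ranges); the pre-clinical block is
12 columns driven by 3 latent factors with loading norm 1 and noise SD
0.25, so three components explain ≈94% of its standardized variance; the
response surface combines linear terms, a saturating housing-vacancy term
(plateau above 12%), and a pre-clinical factor contribution, with
intercept 6.8 and noise SD 0.45 chosen so K centres near 13% — the
national scale of the real outcome — at a signal-to-noise ratio of ≈3.2.
The ground-truth record keeps the surface, the per-group parameters and
closed-form partial effects for additive terms.

What the synthetic studies do *not* emulate: the true joint distribution
of real surveillance and census variables, spatial correlation between neighbouring
communities, measurement error, or correlated economic predictors within
a group. Passing tests therefore demonstrate correctness of the machinery
(estimators, formulas, determinism, directional recovery), not the
substantive policy findings obtainable from real data.

## Problem sizes used in checks

The test suite and the acceptance script run scaled-down studies chosen
as the smallest sizes at which each property is stable: repeated-holdout
sweeps use 10 repeats on ~1,350 communities with the stochastic families
at reduced sizes (BART 25 trees / 120 kept draws, GBM/RF 150 trees), the
scenario battery uses 300 draws per group, and directional recovery is
replicated across 25 (script) or 100 (tests) seeded studies of 50 groups
× 20 communities with 200 draws. These sizes are the package's own
defaults for quick studies; the library defaults above are recommended
for real analyses.

## Known limitations

- The MH sampler explores tree space with GROW/PRUNE only; mixing is
  adequate for small `m` and smooth surfaces but slower than mature BART
  implementations.
- The scenario engine treats jointly perturbed variables as independent;
  correlated shifts need a copula, which is out of scope.
- Chi-squared family selection with equiprobable bins has low power in
  small groups (n < 40); the candidate-order tie-break then matters.
- Δκ is undefined for `K_base = 0` (reported as NaN); this cannot occur
  with the default generator but can with user data whose response hits
  the lower bound.
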