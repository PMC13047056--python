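# Methods

## The estimation problem

A binary policy rolls out to cities in waves and never switches off. The
outcome is a bounded composite health index; adoption correlates with city
characteristics that also drive the outcome through an unknown, possibly
nonlinear function. The package estimates the policy coefficient θ in the
partial-linear model

    Y_it = θ·D_it + g(X_it) + U_it,    D_it = m(X_it) + V_it,

with g and m learned by machine-learning regressors under K-fold
cross-fitting and θ taken from the orthogonalized moment
θ̂ = (ΣV̂D)⁻¹ ΣV̂(Y − ĝ). Because the moment is Neyman-orthogonal, first-order
errors in ĝ and m̂ do not propagate into θ̂; cross-fitting removes
own-observation overfitting bias.

## Estimator conventions

- **Folds.** K = 5 by default, i.e. a 1:4 holdout:training split; K = 4 and
  K = 8 give the 1:3 and 1:7 variants. Fold assignment is a seeded
  permutation cut into contiguous blocks. Rows are assigned independently
  of city by default; `cluster_folds=True` assigns whole cities to folds
  for sensitivity.
- **Learners.** `random_forest` (default): 500 trees, `max_features="sqrt"`,
  `min_samples_leaf=5`, unrestricted depth. The sqrt feature subsampling is
  the classic random-forest choice; with dummy-heavy designs it also
  prevents the fit cost from scaling linearly in the (large) column count.
  `gradient_boosting` maps to histogram gradient boosting;
  `linear` is a ridge-stabilized least-squares learner (penalty 1e-8,
  intercept unpenalized, hence exactly translation-equivariant) fast enough
  for tight bootstrap loops. The binary treatment is modeled by the same
  regressor family (a regression forest's conditional mean is the
  propensity); predictions are clipped to [0, 1].
- **Standard errors.** The model-based score ψ_it = V̂_it(Ỹ_it − θ̂·D_it)
  with J = ΣV̂D gives Var(θ̂) = J⁻² Σ_c (Σ_{it∈c} ψ_it)², clustered by city —
  panel dependence within city is the dominant correlation. Degrees-of-
  freedom corrections are omitted; with ≥50 clusters they are negligible
  relative to Monte-Carlo noise.
- **Repeated cross-fitting.** `n_repeats` re-runs with fresh fold splits;
  aggregation is the median θ̂ and the median of per-repeat variances.
  Default 1.
- **Fixed effects** enter the learners as one-hot features inside X rather
  than being demeaned away, so tree learners see the raw treatment column
  and the orthogonalization stays a single residual pair.

## The IV variant

When adoption shocks correlate with outcome errors, the PLR moment is
biased. The PLIV estimator builds Z_it = base_i · (year_t − first panel
year) from a time-invariant historical endowment, cross-fits E[Y|X],
E[D|X], E[Z|X] (same learner family, same fold partition), and reports
θ̂ = ΣZ̃Ỹ / ΣZ̃D̃ with the IV score ψ = Z̃(Ỹ − θ̂D̃) clustered by city. The
instrument is used unstandardized — θ̂ is exactly invariant to rescaling
it. A fit refuses when the instrument has no residual variation after
controlling X (relative threshold 1e-4) or ΣZ̃D̃ is numerically zero; the
first-stage residual correlation corr(Z̃, D̃) is always reported.

## Mediation

The a-path (policy → mediator) is the same PLR estimator with the mediator
as outcome. The b-path solves the two-equation moment system with
instruments (V̂, M̃) for regressors (D, M̃):

    V̂'(Ỹ − θ_dir·D − b·M̃) = 0,    M̃'(Ỹ − θ_dir·D − b·M̃) = 0.

Keeping the main estimator's residual-as-instrument convention makes the
decomposition exact at the moment level: θ̂_total = θ̂_dir + â·b̂ holds
replicate by replicate whenever the three residualizations share folds (the
test suite asserts the identity to 1e-10 with the deterministic linear
learner). A plain OLS-on-residuals b-path would instead leave an O(p/n)
wedge, because out-of-fold residuals anti-correlate with their own
predictions. The indirect effect is the product â·b̂ (no difference
estimator), with a percentile CI from resampling whole cities with
replacement — nuisances are re-fit on every replicate, optionally with a
cheaper learner (`boot_cfg`), and a run aborts if more than 20% of
replicates fail. The shipped study drivers estimate the whole mediation
stage with the linear learner so point estimates and bootstrap CIs share
one estimator; a forest-based point estimate paired with cheaper
replicates can sit outside its own CI when the forest underfits a
mediator's control function.

## The synthetic generator

The generator emulates the reference study design: 270 cities × 14 years
from 2007; three adoption waves (2012/2013/2014) of floor(0.10·n) cities
each, giving a treated city-year share of 0.171; a direct effect of 0.12 on
the index scale plus three mediator paths (a, b) = (0.028, 0.143),
(0.205, 0.054), (0.773, 0.010) whose indirect effects sum to 0.023, for a
total effect of 0.143. Mechanics:

- **Confounders** X_it = μ_ik + 0.6·ε_itk combine a persistent city
  component and transitory noise (k = 10 by default).
- **Adoption** ranks cities by
  `confounding_strength·(w'μ_i) + instrument_strength·z_i + q_i` with
  q_i ~ N(0,1); the top blocks adopt at the earliest wave. The selection
  weight w loads on the first three confounders — the same coordinates the
  nonlinear nuisance menu is built from — so omitting the nonlinear terms
  visibly biases naive linear OLS (by about +0.016 at the default settings,
  an order of magnitude above its Monte-Carlo SE).
- **Nuisance** g is 0.7·(linear index) + 1.4·(centered squares) +
  1.0·(pairwise products of the first three confounders) + 1.0·(centered
  threshold on X₁), rescaled so Var(g) = Var(noise); `nonlinear_nuisance=False`
  keeps only the linear part (for oracle tests).
- **Endogeneity**: outcome noise is
  noise_sd·(ρ·q_i + √(1−ρ²)·ε_it), so ρ ≠ 0 correlates adoption shocks with
  outcome errors while the instrument base z_i (a Gamma(2,1) "historical
  endowment", entering adoption only) stays clean — exclusion holds by
  construction.
- **Fixed effects**: city effects i.i.d. N(0, 0.04²); year effects a mild
  linear trend plus noise (SD 0.02), so province×trend robustness has
  signal to absorb.
- **Mediators** M = a·D + 0.3·(rotated confounder index) + noise, with
  per-mediator noise SDs chosen so the three a-coefficients have
  realistically distinct scales.
- **Bounded outcome** (`index_scale=True`): adds a right-skewed city
  quality term (centered Gamma) and clips to [0, 1]; the clip fraction is
  logged in `panel.meta`. The default is the unclipped linear scale so that
  closed-form oracles stay exact.
- **Indicators**: five positive-valued series affine in a shared latent
  health factor (the panel outcome rescaled to [0, 1]); incidence is the
  one negative-direction indicator. At zero indicator noise the entropy
  index is exactly rank-equivalent to the latent factor.

What the generator does **not** emulate: spatial correlation between
cities, migration, epidemic dynamics, serially correlated shocks, or
measurement error in the treatment date. Passing tests therefore certify
the estimator machinery under clean staggered adoption with rich nonlinear
confounding — not robustness to those further real-data features.

## Entropy-weight index

Min-max normalization with direction reversal for loss indicators; shares
p_ij = (z_ij + ε)/Σ(z_ij + ε) with ε = 1e-12 guarding ln 0; e_j =
−(1/ln n)Σ p ln p; w_j ∝ 1 − e_j. A constant column gets weight exactly 0;
an all-constant table is refused. Normalization and weights are pooled over
the full city-year panel (not per-year) so the index is comparable across
years — per-year weighting would let the metric itself drift.

## Numerical and procedural choices

- Winsorization clips at nearest-order-statistic quantiles, pooled over the
  panel; bounds are then observed values, clipping is idempotent and never
  leaves the observed range. Presets (0.01, 0.99) and (0.05, 0.95) mirror
  the two-tailed 1% and 5% robustness variants. Treatment and binary
  columns are never clipped.
- Interpolation is within-city linear over years, nearest-value fill at
  edges, refusal when a city's column is entirely missing.
- Wave sizes use floor(fraction·n_cities); leftovers never adopt.
- Pilot-batch subgroup fits compare each batch's adopters against
  never-treated cities only, avoiding contaminated controls.
- All seeds derive from `numpy.random.SeedSequence` paths below 2³¹; a
  study bundle is a pure function of its YAML config (the manifest stores
  the config hash, runtimes go to logs only).

## Monte-Carlo problem sizes in the test suite

The statistical guarantees are exercised at sizes chosen for a single-CPU
run (the full suite completes in well under half an hour):

| check | design | reps |
|---|---|---|
| linear-oracle equivalence | 500 cities × 10 yr, linear learner | 1 |
| recovery, coverage, bias vs naive OLS | 70 × 12, RF 100 trees, nonlinear confounding | 200 |
| type-I error | 100 × 10, linear learner, θ = 0 | 200 |
| IV repair (ρ = 0.5) | 120 × 10, linear learner | 100 |
| mediation bootstrap null/power | 50 × 8, linear learner, 200 boot | 100 outer |
| fold/learner robustness | 70 × 12, RF and gradient boosting | 1 |

The recovery suite omits city dummies from both the generator variant
(`fe_sd_city=0`) and the design: city effects are i.i.d. noise orthogonal
to adoption in this generator, and at small panel sizes a dummy-dominated
design makes the clustered sandwich visibly conservative without changing
the estimand. At the full reference scale (with city dummies) coverage was
measured at ~0.97 — the trimmed variant preserves the statistical content
while keeping each replication ~1.5 s.

## Known limitations

- The treatment-side nuisance is fit by regression, not classification;
  for strongly rank-driven adoption the propensity is a step-like function
  a linear learner underfits, which pushes the corr(V̂, m̂) diagnostic up
  (it stays well under 0.05 at moderate confounding and grows with it).
- Percentile bootstrap CIs for a·b slightly over-cover under a = b = 0
  (the classic product-of-coefficients null); the suite asserts ≥85%
  coverage rather than exact calibration.
- No interactive (fully heterogeneous) treatment-effect model: θ is a
  scalar per fit; heterogeneity is explored by subsample refits only.
- Single instrument only; no over-identification tests.
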