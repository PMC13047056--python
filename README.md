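# paneldml

Double/debiased machine learning for evaluating a binary city-level policy's
effect on a composite public-health index, on staggered-adoption panels.

The package addresses a standard problem in policy epidemiology: a pilot
program (here modeled on smart-city construction pilots rolled out to
Chinese prefecture-level cities in three waves) switches on in different
years for different cities and stays on, adoption is not random, and the
confounders are high-dimensional with unknown, plausibly nonlinear effects
on the health outcome. Difference-in-differences leans on parallel trends;
plain regression leans on a correctly specified control function. The
partial-linear model with cross-fitted machine-learning nuisances needs
neither.

## The model

For city *i* in year *t*, with outcome *Y* (a bounded composite health
index), absorbing treatment *D*, and high-dimensional controls *X*
(control levels and squares, year and city dummies):

    Y_it = θ·D_it + g(X_it) + U_it,      E[U | D, X] = 0
    D_it = m(X_it) + V_it,               E[V | X] = 0

Both conditional expectations ĝ and m̂ are learned by pluggable regressors
(random forest by default) under K-fold cross-fitting, so every prediction
comes from models that never saw the observation. The policy effect is the
Neyman-orthogonal moment estimate that uses the treatment residual as an
instrument for the treatment:

    θ̂ = ( Σ V̂_it·D_it )⁻¹ · Σ V̂_it·( Y_it − ĝ(X_it) )

with influence-function standard errors clustered by city. Around this core
the package provides:

- **`synthetic_panel`** — a staggered-adoption generator with known ground
  truth: adoption propensity loading on confounders and on a historical
  instrument, nonlinear nuisance functions, two-way fixed effects, three
  mediators with tunable a/b paths, and an optional bounded right-skewed
  index outcome.
- **`index_entropy`** — the entropy-weight composite index over
  direction-tagged indicators (min-max normalization, weights proportional
  to 1 − entropy of each indicator's share distribution).
- **`design_prep`** — interpolation, winsorization, quadratic expansion,
  dummy blocks, province×trend terms.
- **`dml_pliv`** — a partial-linear IV variant: a time-invariant historical
  endowment × time trend instrument, all of Y, D, Z residualized on X,
  θ̂ = ΣZ̃Ỹ / ΣZ̃D̃.
- **`mediation`** — a-path (DML with the mediator as outcome), b-path (a
  joint residual-as-instrument moment fit, so total = direct + a·b exactly),
  and a city-block bootstrap percentile CI for the indirect effect a·b.
- **`study_pipeline`** — the full study from one YAML: benchmark
  specification ladder, robustness suite, mediation, subgroup
  heterogeneity, reproducible output bundles.

## Worked example

```python
from paneldml import (DGPConfig, DMLConfig, PrepConfig, generate_panel,
                      true_effects, dml_plr)

cfg = DGPConfig(n_cities=70, n_years=12, theta_true=0.15, fe_sd_city=0.0,
                adoption_waves=((2011, 0.10), (2012, 0.10), (2013, 0.10)),
                confounder_dim=6, mediator_paths={}, mediator_noise_sd={},
                seed=20000)
panel = generate_panel(cfg)           # 840 city-years, nonlinear confounding
res = dml_plr(panel, "PHL", "SCC", PrepConfig(fe_city=False),
              DMLConfig(learner="random_forest",
                        learner_params={"n_estimators": 100}, seed=0))
print(f"theta_hat = {res.theta_hat:.4f} (se {res.se:.4f}), "
      f"CI [{res.ci95[0]:.4f}, {res.ci95[1]:.4f}]")
```

prints

```
theta_hat = 0.1711 (se 0.0109), CI [0.1497, 0.1926]
```

— the cross-fitted estimate recovers the true effect 0.15 within its 95%
confidence interval even though adoption was driven by confounders that
enter the outcome through squares, interactions and a threshold term. Over
200 such panels the interval covers the truth ~96% of the time and the
orthogonalized estimate has smaller mean absolute error than naive OLS
(see `tests/test_acceptance.py`).

The full simulated study at reference scale (270 cities × 14 years, total
effect 0.143) runs from the numbered drivers:

```bash
python analysis/01_simulate_panel.py   # panel + descriptives
python analysis/02_build_index.py      # entropy-weight index
python analysis/03_benchmark.py        # 4-column specification ladder
python analysis/04_robustness.py       # winsor/FE/policy/IV/fold/learner variants
python analysis/05_mediation.py        # a/b paths + bootstrap CIs
python analysis/06_heterogeneity.py    # region/size/regulation/batch subgroups
```

Small tables land in `results/`; bulky intermediates in `scratch/`.

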