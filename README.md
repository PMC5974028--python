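# saplingniche

Climate-niche models of conifer sapling height growth for the Pacific
Northwest, and their links to ecosystem function.

Height growth of young conifers is strongly climate-determined: across
provenance trials (common gardens replicated along wide climatic
gradients), the same populations grow to very different heights at
different sites, and those differences track evapotranspiration and
growing-season temperature sums. `saplingniche` implements the full
analysis chain for quantifying this: a growth-trajectory model whose
parameters are climate functions, exhaustive screening of climate-variable
subsets, cross-validated accuracy by species, and correlation of predicted
height with forest-inventory measures of productivity, biomass and
diversity. It is aimed at forest geneticists and ecologists working with
provenance-trial and inventory-plot data.

## The model

Sapling height (m) at age *x* (years, ≤ 25) follows the exponential limb
of a Chapman–Richards curve,

```
h(x) = θ₁ (e^{θ₂ x} − 1),
```

where the scale θ₁ (m) and relative growth rate θ₂ (1/yr) are linear
functions of site climate:

```
θ₁ = a₁₀ + Σⱼ a₁ⱼ cⱼ,    θ₂ = a₂₀ + Σⱼ a₂ⱼ cⱼ.
```

The cⱼ are drawn from 12 modelling variables — Hargreaves reference
evaporation (*Eref*), degree-days above 5 °C (*DD5*), degree-days below
18 °C (*DD_18*), mean annual temperature (*MAT*), and seasonal splits of
DD5/DD_18 — with all degree-day and Eref values scaled by 1/100. With
i.i.d. Gaussian errors the maximum-likelihood fit is nonlinear least
squares; the model applies only where annual DD5 > 100 degree-days.

Variable choice proceeds in two stages: PLSR screening of a large climate
pool (leave-one-out component choice, |loading| ≥ 0.4), then all-subsets
regression of the 12 retained variables (2¹² = 4,096 models) on a
log-linearized form `ln(h + θ̂₁) = ln θ₁ + θ₂ x`, ranked by AIC.
Accuracy is summarized by ten-fold cross-validated bias and RMSE per
species; inventory plots (≥ 70% conifer) link predicted height at the
standard age of 8 years to productivity class, aboveground dry biomass
and alpha tree/species diversity via Pearson correlations, full and
95%-trimmed.

Because the compiled trial data are not public, the package ships
first-class synthetic generators that reproduce the study structure
(616 populations, 15 species, ages 1–25, 0.65 m height noise, ~44,000
inventory plots) from a published ground-truth coefficient set, so every
stage runs and is tested end to end.

## Worked example

```python
import numpy as np
from saplingniche import (GeneratorConfig, gen_provenance_dataset,
                          fit_niche_model, reference_annual_model,
                          tenfold_cv)

truth = reference_annual_model()          # published annual-variable model
data = gen_provenance_dataset(GeneratorConfig(seed=42))
model = fit_niche_model(data, truth.spec)
print("theta1:", np.round(model.theta1_coeffs, 5))
print("theta2:", np.round(model.theta2_coeffs, 6))
print(f"pseudo R2 = {model.pseudo_r2:.4f}, RMSE = {model.rmse:.4f} m")
report = tenfold_cv(data, truth.spec, seed=42)
print(f"CV bias = {report.overall_bias:+.4f} m, CV RMSE = {report.overall_rmse:.4f} m")
```

prints

```
theta1: [ 2.77826  0.0626  -0.02073 -0.14849]
theta2: [ 0.10007  -0.000408]
pseudo R2 = 0.9845, RMSE = 0.6670 m
CV bias = +0.0287 m, CV RMSE = 0.6705 m
```

The fitted θ₁ coefficients (intercept, DD5, DD_18, Eref) and θ₂
coefficients (intercept, DD5) recover the generating values
(2.801085, 0.061629, −0.02025, −0.15363) and (0.099673, −0.00037) within
sampling error; the near-zero cross-validated bias and ~0.67 m RMSE match
the 0.65 m noise injected by the generator. Positive bias means
underestimation.

The same pipeline is scriptable from the shell:

```sh
saplingniche --outdir out --seed 42 all   # simulate → screen → search →
                                          # fit → validate → scenarios →
                                          # correlate
```

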