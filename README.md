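# phylomass

Phylogenetically informed body-mass estimation for extinct taxa from
femoral measurements.

Body mass underlies nearly every inference about an extinct animal's life
history and ecology, but classic allometric regressions treat species as
independent samples. When close relatives cluster in trait space — as the
giant subfossil lemurs of Madagascar do — that assumption inflates
predictions. `phylomass` fits the allometry as a **phylogenetic generalized
least squares (PGLS)** regression, letting a tree-derived covariance
down-weight related species, and propagates that same covariance into 95%
prediction intervals for fossil specimens.

The model is

```
ln(BM) = β₀ + β₁ ln(FCSA) + ε,   ε ~ N(0, σ² V(λ)),
V(λ) = λ C + (1 − λ) diag(C)
```

where BM is body mass, FCSA is femoral cortical cross-sectional area (mm²),
C is the phylogenetic variance–covariance matrix (shared root-to-ancestor
branch lengths), and Pagel's λ ∈ [0, 1] measures phylogenetic signal
(0 = star tree / ordinary least squares, 1 = full Brownian motion).
λ is estimated by profile maximum likelihood; candidate models
(`BM~FCSA`, `BM~FL`, `BM~FCSA+FL`) are ranked by AIC; fossil specimens are
predicted with leverage-aware prediction limits and pooled into
species-level weighted means.

The package is aimed at comparative morphologists and paleontologists:
it ships the subfossil lemur femoral specimen table (127 femora across 16
species groups, two data sources) with published estimates for
cross-checking, and a synthetic-data generator that reproduces the
statistical structure of an extant reference dataset so every stage of the
pipeline is testable end to end.

## Worked example

Simulate a reference dataset of 62 extant species plus four fossil species,
fit the allometry, and predict the fossils:

```python
from phylomass import (SimulationConfig, simulate_dataset, fit_model,
                       predict_specimens, species_weighted_mean)
from phylomass.predict import records_to_frame

ds = simulate_dataset(SimulationConfig(n_extant=62, n_fossil_species=4,
                                       specimens_per_species=(2, 3), seed=42))
fit = fit_model(ds.traits, ds.tree, "BM~FCSA")
print(fit.equation())
# ln(BM) = 1.25 x ln(FCSA) + 3.35          (generating values: 1.26, 3.48)
print(f"lambda={fit.lambda_hat:.3f}  AIC={fit.aic:.1f}  adjR2={fit.adj_r2:.3f}")
# lambda=0.699  AIC=-5.7  adjR2=0.988

preds = records_to_frame(predict_specimens(fit, ds.specimens))
print(species_weighted_mean(preds).round(2).to_string(index=False))
# species  nT  nJ  N  mean_fcsa_mm2  mean_bm_kg  mean_lower95_kg  mean_upper95_kg
# fossil1   0   0  3         197.02       20.89            11.41            38.23
# fossil2   0   0  3         400.92       50.66            27.62            92.92
# fossil3   0   0  2          66.70        5.40             2.95             9.87
# fossil4   0   0  2         190.98       20.07            10.97            36.73
```

The coefficients are on the natural-log scale with mass internally in
grams; reported masses and limits are kg. Each species row pools its
specimens with equal weight (`nT`/`nJ` count specimens per source for the
packaged lemur data). The true simulated masses here are 22.7, 113.6, 4.2
and 24.4 kg — three of four inside their 95% limits, as expected for
intervals calibrated at 95%.

The same pipeline runs from the shell:

```bash
phylomass simulate --n-extant 62 --seed 42 --out sim/
phylomass run-all --config config.yaml      # fit + predict + aggregate + compare
```

For the packaged subfossil lemur application:

```python
from phylomass.datasets import load_subfossil_specimens, reference_allometry
intercept, slope = reference_allometry()    # (3.4847, 1.2606)
```

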