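# smveg

Soil-moisture–vegetation coupling analysis for basin-scale eco-hydrology.

In semi-arid basins, soil moisture (SM) and vegetation condition regulate
each other: moisture limits canopy growth, and canopy cover in turn shields
and recharges the soil store. `smveg` is a toolkit for quantifying that
interaction from multi-source data — field soil physicochemistry, optical
and radar imagery, and gridded vegetation products — for researchers and
watershed managers who need wall-to-wall maps rather than point samples.

The pipeline has five analytical cores:

1. **Layered SM inversion.** Per depth layer (0–10, 10–20, 20–30 cm),
   predictors significantly correlated with measured moisture (Pearson,
   p < 0.05) feed three regression families — significance-based stepwise
   (SMLR), ridge with cross-validated penalty, and partial least squares —
   fitted on a 4:1 site split and compared on validation R² under the error
   gates RMSE < 0.05, MAE < 0.02, MAPE ∈ [0, 20)%.
2. **Composite vegetation index.** NPP, LAI and the best of seven spectral
   indices (chosen by KMO sampling adequacy, Bartlett sphericity and a
   0.6 correlation gate) are combined through correlation-matrix PCA with
   varimax rotation: per-indicator weights are the component score
   coefficients mixed in proportion to the rotated sums of squared loadings
   (λ_k/Σλ) and normalized to sum to one, giving
   VEG = w₁·NPP + w₂·LAI + w₃·index.
3. **Pixel-wise Spearman correlation** between the annual SM and VEG
   series, with t-based significance and area accounting.
4. **Coupling coordination.** C = 2√(VEG·SM)/(VEG+SM),
   T = α·VEG + β·SM (α = β = 0.5), D = √(C·T), classified into five levels
   from Extreme Disorder (0, 0.2] to Highly Coordinated (0.8, 1.0].
5. **Driver screening.** A Gini-impurity random forest over eight drivers
   (population density, elevation, slope, aspect, temperature,
   precipitation, land-surface temperature, potential evapotranspiration)
   ranks their importance for D: per split,
   gain = Gini(parent) − (n_l/n)·Gini(left) − (n_r/n)·Gini(right),
   accumulated per feature over all trees and normalized to shares.

A synthetic basin generator (`smveg.synthetic`) produces all inputs with
known structure — a north-dry/south-wet gradient, summer-peaking seasonal
cycles, linear soil-property→moisture truth with configurable noise,
cross-correlated vegetation descriptors, and drivers with a planted
importance order — so the full chain runs and is tested without any
download. See `docs/methods.md` for the model details and their limits.

## Worked example

```bash
smveg run-all --seed 1 --out run1
```

runs simulate → composite → invert → veg → correlate → couple → importance
on the default 48×48 synthetic basin (120 sites, 2017–2024 monthly layers)
and prints, among the products written to `run1/` (`summary.json`,
`samples.csv`, SM/VEG/ρ/D rasters, weights and importance tables):

```
"chosen_index": "NDVI",
"veg_weights": {"NPP": 0.333, "LAI": 0.333, "NDVI": 0.333}
```

The three indicators are nearly equi-correlated in this synthetic basin, so
the PCA assigns them equal weight. The selected surface-layer model

```
"0-10": {"method": "SMLR", "intercept": -0.121,
         "coefficients": {"P_cap": 0.0134, "BD": 0.0829}}
```

recovers the generating equation (−0.105 + 0.013·P_cap + 0.084·BD) up to
the 0.01 measurement noise, with validation R² = 0.98, RMSE = 0.008,
MAE = 0.006, MAPE = 1.1% — all inside the selection gates. Downstream,

```
"correlation_proportions": {"0-10": {"sig+": 0.61, "sig-": 0.01, "nonsig": 0.37}}
"coupling_class_proportions": {"0-10": {"Moderately Coordinated": 0.83, ...}}
"driver_importance": {"0-10": {"lst": 0.149, "pet": 0.143, ...}}
```

positive SM–VEG correlation dominates (the two share the wetness gradient),
one coordination class covers most of the basin, and the two drivers
anchored most strongly to the wetness field (LST, PET) top the importance
ranking at every depth.

Each stage is also exposed on its own (`smveg simulate`, `veg-index`,
`composite`, `invert`, `veg`, `correlate`, `couple`, `importance`), and the
library functions accept in-memory grids and data frames directly.

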