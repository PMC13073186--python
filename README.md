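# foodcarbon

Household food-related carbon footprints and the income threshold in their
relationship with household income.

Rising incomes reshape diets — less cereal, more animal-source food — and
with them the greenhouse-gas footprint of what households eat. This package
implements, for household panel surveys of the CHNS type (72 h dietary
recall, four waves, provinces as clusters), the full analysis chain that
question requires:

* **accounting** — annualize recall records, apply median life-cycle (LCA)
  emission factors (kg CO2eq per kg of food), aggregate to household tons
  CO2eq per year and to nine food categories; sample filters (negative-income
  drop, two-sided 1% winsorization, balanced-panel restriction);
* **threshold regression** — the fixed-effects panel threshold model

      ghg_it = β0 + β1·inc_it·1{inc_it ≤ γ} + β2·inc_it·1{inc_it > γ}
               + Z_it θ + μ_i + λ_t + ε_it

  with γ estimated by concentrated least squares over the observed income
  support, bootstrap sup-F tests for the number of thresholds, likelihood-
  ratio confidence sets {γ : LR(γ) ≤ −2 ln(1−√(1−α))}, and CR1
  province-clustered standard errors;
* **diet quality** — per-capita daily intake versus the Chinese Food Guide
  Pagoda (2022) ranges: adequacy labels (insufficient / adequate / excess)
  and the non-negative midpoint-normalized deviation score, with grouped
  income regressions below/above the threshold;
* **synthetic data** — a CHNS-like balanced panel generator with a known
  piecewise income effect, so every stage is testable against ground truth;
* **pipeline** — one reproducible run (config + seed → identical artifacts)
  with a CLI: `foodcarbon simulate | footprint | fit | run-all`.

It is written for applied researchers in food/environmental economics and
nutritional epidemiology who want a tested, reusable implementation of this
estimator chain rather than one-off scripts.

## Worked example

```python
from foodcarbon import (SyntheticConfig, generate_panel, filter_and_winsorize,
                        estimate_threshold, threshold_number_test, format_report)

panel = generate_panel(SyntheticConfig(seed=1))     # 2072 households x 4 waves
panel = filter_and_winsorize(panel, enforce_balance=True)
fit = estimate_threshold(panel)
test = threshold_number_test(panel, n_boot=200, seed=1)
print(format_report(fit, test))
```

On the default synthetic panel (true threshold 6.55, true slopes
0.0547/0.0203 tons per 10,000 yuan) this prints:

```
Panel threshold regression (household & year FE, cluster-robust SEs over 12 provinces)
threshold gamma = 6.6655  95% CI [6.3074, 6.8544]
  1 threshold(s): F = 27.84, bootstrap p = 0.000 (200 reps)
  2 threshold(s): F = 2.99, bootstrap p = 0.935 (200 reps)
  3 threshold(s): F = 2.72, bootstrap p = 0.965 (200 reps)
variable              coef  t-stat
income_low          0.0635*** (5.47)
income_high         0.0232*** (3.61)
hhsize              0.9123*** (33.05)
...
N = 8288   adj. R2 = 0.167
```

Read: the data support exactly one income threshold (the 0-vs-1 bootstrap
p-value is below 0.05; 1-vs-2 and 2-vs-3 are not), estimated at 6.67 in
CPI-adjusted 10,000-yuan units with the true value 6.55 inside the 95% LR
set; the marginal emission effect of income is about three times larger
below the threshold (0.063 t per 10,000 yuan) than above it (0.023 t).
Footprints here use the seven published median LCA factors; items whose
factors are unpublished must be supplied explicitly
(`EmissionFactorTable.default(plant_placeholder=...)`).

The numbered scripts under `analysis/` run the same chain step by step
(simulation, accounting round-trip check, threshold fit, consumption
structure, diet quality) and write their tables under `results/`.

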