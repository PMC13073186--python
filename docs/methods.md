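# Methods

`foodcarbon` implements a household food-emissions analysis chain: life-cycle
(LCA) emission-factor accounting over dietary-recall records, a fixed-effects
panel threshold regression of emissions on income, and diet-quality scoring
against recommended intake ranges — exercised end-to-end on a synthetic,
CHNS-like household panel with known ground truth.

## 1. Footprint accounting

A 72 h dietary recall records item-level amounts `a` (kg). Annual consumption
is `a × 8760/window` (365/3 × a for the standard 72 h window). Household
emissions are

    ghg_i = Σ_items annual_kg × EF_item / 1000     [tons CO2eq/year]

with `EF` the median cradle-to-retail LCA factor in kg CO2eq per kg. The
default factor table carries exactly the seven published median factors
(beef 51.7, pork 9.8, poultry 7.8, eggs 4.2, milk 2.3, wheat 1.3, rice 3.1).
Vegetable and fruit factors are published only as "below 1 kg CO2eq/kg", so
the table refuses to invent them: users must pass an explicit placeholder or
their own entries, and an unmapped item raises by default (an optional
drop-with-warning mode exists; silent zeros would bias footprints downward).
Only indirect (production-chain) emissions are in scope; cooking and storage
energy are not.

Items map to nine categories (cereal, tuber, vegetables, fruit, livestock,
poultry, eggs, aquatic, dairy); "animal food" is the composite of the last
four meat/egg/fish groups plus livestock and poultry. Category shares are
reported under two labelled conventions — ratio of mean amounts, and mean of
household-level shares — because published group shares are not simple
amount ratios and the original weighting is unstated; neither convention is
asserted as "the" published one.

**Sample filters.** Rows with negative income are dropped first; income and
emissions are then winsorized two-sided at 1%; a balanced-panel restriction
can be enforced last. Winsorization clamps by *order statistics* (the
`scipy.stats.mstats.winsorize` convention: the lowest/highest ⌊n·0.01⌋
values are replaced by the nearest retained order statistic). We chose this
over interpolated-quantile clamping because it is exactly idempotent and, on
100 distinct values at 1%, gives the textbook result (1 → 2, 100 → 99);
interpolated quantiles satisfy neither. Winsorizing refuses samples below
100 rows, where 1% tails are meaningless.

## 2. Panel threshold regression

For household *i*, wave *t*:

    ghg_it = β0 + β1·inc_it·1{inc_it ≤ γ} + β2·inc_it·1{inc_it > γ}
             + Z_it θ + μ_i + λ_t + ε_it

with income in CPI-adjusted 10,000-yuan units, controls Z (household size,
child and elderly shares, head's age, education, marital status; the age
square is available behind a flag but excluded by default), household fixed
effects μ absorbed by within-demeaning, and year effects λ as wave dummies.
Note the conditional mean is deliberately *discontinuous* at γ (a regime
model, not a kink).

**Concentrated search.** For each candidate γ the slopes are profiled out by
OLS and `S1(γ)` (the residual sum of squares) recorded; γ̂ is the argmin,
ties broken to the smallest candidate. The candidate grid is every unique
observed income between the 1st and 99th percentiles whose split leaves at
least max(5% of observations, parameters + 1) in each regime. Since the
two-regime design spans `[inc, inc·1{inc≤γ}, Z, wave dummies]` and only the
low-regime column depends on γ, all γ-invariant columns are orthonormalized
once (rank-revealing QR) and each candidate costs a single projection; the
search is algebraically identical to refitting at every candidate, which the
tests verify against dense least-squares solves.

**Number of thresholds.** Sequential sup-F tests, up to three thresholds:

    F_m = (S_{m-1} − S_m) / σ̂²,   σ̂² = S_m / (N − n_households − k)

with S_{m-1} the null SSR holding previously found thresholds fixed and S_m
minimized over the remaining feasible grid (every regime keeps the minimum
share). A config switch (`dof_adjust=False`) reproduces the plain S_m/N
variance normalization. The printed form of the test statistic in the source
literature would be identically zero at γ̂; the implemented F uses the
no-threshold (linear FE) SSR as S0, which is the standard statistic for this
estimator. p-values come from a fixed-regressor residual bootstrap:
household-level residual *blocks* of the null model are resampled with
replacement (requires a balanced panel, which the filters enforce) and the
full search is re-run on each draw with regressors held fixed;
p = fraction of bootstrap F ≥ observed F. A province-level variant is
provided as a cluster wild (Rademacher sign-flip) bootstrap — true
province-block resampling would break the alignment between fixed regressors
and resampled blocks because provinces differ in size. A perfectly fitting
alternative (S_m = 0) is treated as maximal evidence (F = ∞, p = 0). After a
threshold is added, earlier thresholds are refined one pass, each re-searched
holding the others fixed; each stage's F holds the prior thresholds at their
conditioning values.

**Threshold confidence set.** LR(γ) = (S1(γ) − S1(γ̂))/σ̂²; the level-(1−α)
set is {γ : LR(γ) ≤ −2 ln(1 − √(1−α))} (7.3523 at α = 0.05), reported as the
interval hull. Because S1 is a step function constant between adjacent
observed incomes, an accepted candidate x₍ₖ₎ represents the whole interval
[x₍ₖ₎, x₍ₖ₊₁₎); the upper endpoint is therefore extended to the next
observed support value, without which a true threshold lying between
observations would be missed systematically at low noise.

**Coefficient inference.** CR1 cluster-robust sandwich at the province
level: c·(X'X)⁻¹(Σ_g X_g'e_g e_g'X_g)(X'X)⁻¹ with
c = G/(G−1)·(N−1)/(N−k); t-statistics are referred to a t distribution with
G−1 degrees of freedom. With singleton clusters this reduces exactly to
HC1 (verified against statsmodels). The within adjusted R² is
1 − (S1/(N−n_h−k)) / (TSS_w/(N−n_h)). Collinear regressors (e.g. a control
that is an exact function of the wave) are detected by pivoted QR and
dropped with a warning rather than silently inflating the covariance.

## 3. Diet quality

Per-capita daily intake is `annual_kg × 1000/365/hhsize` (g/day). Against a
recommended range [L, U] with midpoint m = (L+U)/2, the deviation score is
(L−c)/m below, 0 inside, (c−U)/m above — non-negative, continuous, piecewise
linear with slopes −1/m, 0, +1/m. Values exactly on a bound count as
adequate (the labels are defined by strict violation of a limit). The
default ranges are the Chinese Food Guide Pagoda (2022) intervals for six
aggregated categories (cereal 200–300, tuber 50–100, vegetables 300–500,
fruit 200–350, animal food 120–200, dairy 300–500 g/day).

Grouped income regressions (amounts in kg, shares in percentage points,
deviation scores) split the sample at the estimated threshold and reuse the
main model's structure — household demeaning, wave dummies,
province-clustered CR1 errors — since the original specification for these
auxiliary regressions is not restated in full; a pooled (no-FE) option
exists. Groups under 30 observations are refused. Group-difference tests
regress the outcome on a group indicator with cluster-robust errors;
zero-variance outcomes return NaN flagged as degenerate rather than a
fabricated p-value.

## 4. Synthetic data generator

The generator emulates the structure of the CHNS extract the analysis is
designed for: a balanced panel, 2072 households × 4 waves (8288 rows,
matching the reference sample size) in 12 provinces, with

* income: lognormal, ln inc = 0.9 + 0.12·t + a_i + e_it with persistent
  household component (sd 0.5) and transitory noise (sd 0.6). This puts
  ~10% (first wave) to ~21% (last wave) of observations above the default
  threshold of 6.55, bracketing the reference low/high split (≈13% above);
* emissions: the two-regime model above with slopes 0.0547/0.0203 tons per
  10,000 yuan, threshold 6.55, intercept and control coefficients set to the
  reference point estimates; year effects drift upward (0, .05, .15, .25 t);
  household effect sd 0.7, province effect sd 0.3, idiosyncratic noise sd
  1.0 t — a realistic noise scale at which a single study-size replication
  yields a within adjusted R² of ≈ 0.17 and regime slopes of the right
  magnitude, while threshold confidence sets remain honestly wide;
* demographics with modest within-household time variation (size jitter,
  child/elderly counts redrawn, ±1 year of survey-timing noise on the head's
  age, occasional education increments and marital transitions) so that
  control coefficients stay identified under household fixed effects — a
  time-constant regressor is absorbed;
* a validity check refusing configurations with fewer than 10% of
  observations on either side of the threshold (unidentifiable).

Recall records are generated by *inverting* the accounting chain: each
household-wave's emission budget max(ghg, 0)×1000 kg CO2eq is allocated over
eleven representative items with an animal-food emission share rising in
income up to the threshold (0.35 + 0.045·min(inc, γ), capped at 0.72),
multiplicative lognormal jitter on item shares, and item kilograms =
CO2 budget × share / factor. The round trip footprint(annualize(records)) =
max(ghg, 0) then holds to floating-point accuracy; the clip matters only for
the rare noise-driven negative ghg draws (none at default scale in a typical
seed, a handful at most), and the round-trip identity is stated against the
clipped value. Factors for items whose medians are unpublished (potato,
vegetables, fruit, fish) are explicit synthetic placeholders carried in the
table's provenance tag.

What the generator does **not** emulate: survey weights and attrition,
measurement error in the recall instrument, province-specific tastes beyond
a random cluster shift, and any amount-led dietary upgrading — because item
kilograms are derived from the emission budget, a composition shift toward
emission-dense animal foods *lowers* total kilograms as income rises, the
opposite of amount-led survey data. Passing tests therefore demonstrate that
the estimators recover a known data generating process of the right scale
and shape, not that the substantive findings of any real survey would
replicate.

## 5. Simulation-study problem sizes

* Bootstrap test size: 200 Monte-Carlo panels of 200 households under an
  equal-slopes DGP, 99 bootstrap draws each; the empirical rejection rate at
  nominal 5% is checked against [2%, 8%].
* Recovery: 100 panels of 1000 households at slopes 0.0547/0.0203 and
  threshold 6.5 with noise sd 0.1 t ("small noise" recovery conditions);
  checked: ≥90% coverage of the 95% LR set and ≤10% mean relative slope
  bias.
* Round trip: one 500-household panel, max relative error ≤ 1e-9.

These sizes give the checks enough replications to be meaningful while
remaining desk-scale (the full suite runs in minutes on one CPU).

## 6. Known limitations

* The LR confidence set uses the homoskedastic asymptotic critical value;
  no heteroskedasticity-robust LR scaling is implemented.
* Multi-threshold search is sequential-with-refinement, not joint; at most
  three thresholds.
* Kink (continuous-threshold) models and endogenous-regressor threshold
  estimators are out of scope.
* The household-block bootstrap requires a balanced panel; unbalanced panels
  must use the province wild scheme.
* CPI deflation is assumed done upstream (income enters in CPI-adjusted
  levels, in 10,000-yuan units; levels rather than logs because the
  reference threshold is stated in yuan).
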