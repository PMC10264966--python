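# Methods

## Scope and shape of the analysis

The package turns respirometry and grazing-assay measurements into a
qualitative prediction of how consumer–resource interaction strength
responds to warming, in five stages: raw series → per-capita rates →
fitted thermal models → energetic balances and mismatch regions → CREB
trend and its concordance with measured interaction strength. Every stage
is usable on its own; `pipeline.run_all` chains them.

## Rates from raw measurements

Each respirometry vial contributes one OLS slope of oxygen (mg O₂ L⁻¹)
against time (min). Per-capita rate = ±(vial slope − mean control slope
from the *same temporal block*)/denominator, negative-signed for
respiration so oxygen consumption is positive; the denominator is cell
density for algae and live individuals at assay start for the consumer.
Block-matching is a hard contract: a missing control block raises rather
than pooling, because control drift is a block-level nuisance. Negative
corrected rates (weak respirers whose control mean exceeds the vial slope)
are flagged but retained — truncation would bias the TPC fit low.

Grazing assays give per-capita raw ingestion
`rI = (D_T0 − D_Tend + (mean C_Tend − mean C_T0)) / (y·t)` in
cells mL⁻¹ h⁻¹ per consumer; the control term credits consumption masked
by algal growth (or debits settling). Energy conversions: respiration ×
14.06 J per mg O₂ × 60 min h⁻¹; ingestion × per-cell energy × assimilation
efficiency (0.14 on *Chlamydomonas*, 0.10 on *Desmodesmus*) × 1000 mL L⁻¹
(the single place the mL→L change happens). Unit tags travel with every
estimate and cross-unit arithmetic raises.

## Thermal performance curves

Unimodal rates are fit to the high-temperature-inactivation
Sharpe–Schoolfield form (see README for the equation). Choices that
matter:

- **Tref = 20 °C** by default. `Ea`, `Eh`, `t_h`, `Topt` are invariant to
  it; only `r_Tref` rescales, so every balance result is Tref-independent.
- **Parameterisation**: internally `(r_Tref, Ea, Eh − Ea, t_h)` with
  `Eh − Ea ≥ 1e−3`, which keeps `Eh > Ea` (and hence a well-defined
  optimum) throughout the search.
- **Multistart**: 20 starts — one data-driven (optimum near the empirical
  argmax) plus seeded random draws with `Ea ∈ [0.2, 3]` eV,
  `Eh ∈ (Ea + 0.1, 25]` eV, `t_h ∈ [280, 330]` K, `r_Tref` log-uniform
  about the data scale. These brackets cover all plausible plankton values
  with margin. Solver bounds are wider (`Ea ≤ 12`, `Eh − Ea ≤ 60`,
  `t_h ∈ [270, 350]` K). Bounded trust-region least squares with
  `xtol = ftol = gtol = 1e−15`; the reported fit has minimal SSE among
  converged starts. Near-tied optima with diverging parameters set a
  `flat_sse_landscape` flag; data with no post-optimum decline pin `t_h`
  at its bound and set `no_high_temperature_decline` instead of
  pretending the inactivation limb is identified.
- **Bootstrap**: case resampling of replicate rows with replacement,
  refit from the point estimate, percentile intervals; defaults
  `n_boot = 999` at 95%. `n_boot = 0` returns the degenerate interval;
  >20% failed refits warns that intervals may be wide.

Ingestion (linear with temperature, or flat) is OLS with an automatic
zero-slope refit: if the slope's p-value is ≥ α = 0.05 the rate is treated
as temperature-independent and the intercept becomes the sample mean —
the standard treatment when grazing shows no thermal dependence.

Predictions are evaluated on an inclusive fixed-step grid, 0.001 °C by
default (14–42 °C → 28001 points).

## Balances, mismatch temperatures, regions

The balance ratio is masked (NaN) wherever the loss curve is ≤ 0, with
the masked fraction reported.

`Tm` prefers the *lowest interior local maximum* of the ratio and flags
when a grid-edge value exceeds it. Rationale: when the loss TPC collapses
past its optimum inside the grid (deactivation energies of ~20 eV make
respiration fall near zero by 42 °C), the raw gain/loss ratio diverges at
the edge; that blow-up is a division artefact of the reconstruction, not a
performance optimum, and the flagged report keeps the distinction visible.
A balance with no interior maximum (the monotonically declining consumer
case) correctly reports the boundary argmax with a boundary flag.

`Tc` is the lowest downward crossing of ratio = 1, located by adjacent
sign change and refined by linear interpolation (sub-grid precision,
matching two-decimal published crossover values); a balance that never
reaches 1 gets an `always_deficit` flag instead.

Derivatives for region work use centred finite differences after a
moving-average smoothing window of 0.5 °C, so instrument-scale wiggles
cannot fragment the visibly contiguous regions. Region 1 = opposite
derivative signs, region 2 = both negative; intervals are reported
exhaustively. One consequence worth knowing: with a constant ingestion
line and a consumer respiration optimum inside the assay range
(~29.4 °C), the consumer balance recovers slightly above that optimum, so
the *Desmodesmus* pair acquires a second, high-temperature region-1
interval in addition to the reported low-temperature one. The onset
(lowest) interval is the scientifically meaningful one and is what the
acceptance checks assert.

The CREB is `ln EB_consumer − ln EB_resource` on the common grid,
restricted to where both balances are positive (antisymmetric by
construction). Its trend is classified from the smoothed derivative with
threshold ε = 1% of the CREB range per °C: all below −ε declining, all
above +ε increasing, −then+ U-shaped, +then− hump-shaped, never outside
±ε flat. Trend → predicted interaction-strength trend: declining →
decreasing, increasing → increasing, U-shaped/flat →
constant-or-increasing with an explicit indeterminate-direction flag.

## Interaction strength

`IS = ln(N/D)/(y·t)` per treatment vial, with `N` the same-block control
mean at assay end and `t` in hours (150 min → 2.5 h). Records from both
pairs enter one OLS with temperature × species interaction; the
interaction test uses Type II sums of squares (identical to Type I in the
balanced design, robust to an occasionally dropped outlier replicate).
Per-pair slopes come from per-pair OLS. Outliers may be excluded only via
an explicit replicate-id list in the pipeline config; every exclusion is
logged with a reason code. Concordance: a significant slope is compared by
sign with a directional prediction; a non-significant slope agrees with a
constant-or-* prediction and is inconclusive against a directional one.

## What the synthetic generators emulate — and what they do not

The generators reproduce the *design* of the assays: two temporal blocks ×
3 replicates, matched controls at each of 8 temperatures (14–42 °C for
algae, 14–36 °C for the consumer), 1-min oxygen readings over 30 min,
150-min grazing assays, 5 grazers per vial with an optional death rate
exercising the live-count denominator. Rates come from curve summaries:
TPCs rebuilt from `(Ea, Eh, Topt, MRP)`, ingestion lines pinned so the
consumer balance crosses 1 at its published crossover temperature (the
intercepts are not published; pinning makes them, and every anchored
quantity, independent of the per-cell energy constant).

Noise model: additive Gaussian on oxygen slopes (default SD = 10% of the
organism signal at the optimum), a common Gaussian control drift per block
(SD 5e−4 mg O₂ L⁻¹ min⁻¹), multiplicative log-normal measurement error on
cell densities (unit mean, CV 0.05), and Gaussian residuals on
interaction-strength draws (SD 0.005 h⁻¹, ~30% CV at mid-gradient levels,
matching the raw-point scatter such assays show). Control density drift is
a signed fraction per hour, default 0 (dark assays, starved cells). With
all noise zero the full pipeline reproduces generating parameters to
machine precision — the round-trip contract the tests enforce.

Two honest gaps. First, the ingestion-energy line and the
interaction-strength line are different transforms of the same underlying
densities, so no single density-generating process can encode both
published slopes exactly; pair presets therefore carry both lines and two
dedicated generators (`generate_ingestion_experiment`,
`generate_is_experiment`). Second, the per-cell energy constants
(1e−6 / 4e−7 J cell⁻¹) and oxygen-assay set densities (2e4 / 2e5
cells mL⁻¹) are documented placeholders chosen for physically plausible
signal sizes; anchored and ratio-based results cancel them, absolute
energy levels do not. Passing tests therefore demonstrate correctness of
the *procedure* under the stated design and noise structure, not fidelity
to any particular laboratory's raw data: real assays add serial
correlation within oxygen traces, block-by-temperature interactions, and
heteroscedastic counting error that the generators deliberately omit.

## Problem sizes and defaults used in the checks

Stochastic checks use 50 seeded replications per scenario (8 temperatures
× n = 6, CV 10%), 20 multistarts per fit, and 200 bootstrap resamples per
interval when empirical coverage is measured; deterministic checks use the
0.001 °C grid. Published summary parameters are printed rounded, so
reconstructed mismatch temperatures are asserted to ±0.5 °C. Where the
consumer respiration optimum is printed inconsistently across tables and
captions (29.40 / 29.4 / 29.45 °C), the tabulated 29.40 is taken as
canonical.

## Known limitations

- No population-dynamics forward model: the Dynamic Index is a short-term
  log response ratio, not an equilibrium interaction coefficient.
- Oxygen series are assumed to arrive in mg O₂ L⁻¹; conversion from
  percent saturation is out of scope.
- No AIC competition among candidate TPC forms; the Sharpe–Schoolfield
  model is taken as given. No weighted or heteroscedastic regression.
- Bacterial respiration in algal vials is not modelled (assumed
  negligible).
- Trend classification on fitted (rather than reconstructed) curves
  inherits fit noise: near-threshold derivative excursions can flip a
  declining CREB to U-shaped for individual noisy seeds.
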