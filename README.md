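# thermomatch

Thermal-mismatch energetics for consumer–resource pairs: from raw assay
measurements (or synthetic equivalents) to per-capita physiological rates,
Sharpe–Schoolfield thermal performance curves, energetic gain/loss
balances, thermal-mismatch classification, the consumer–resource energetic
balance (CREB), and interaction-strength regression.

## The problem

Warming shifts every biological rate at once, and rarely by the same
amount. Whether a consumer keeps suppressing its resource as temperature
rises depends on how its energy *gain* (ingestion) and energy *loss*
(respiration) move relative to each other — and relative to the same
balance in the resource (net photosynthesis vs. respiration). This package
implements that energetic-mismatch analysis for freshwater
plankton systems (a *Daphnia* grazer on two green algae), for ecologists
who want a mechanistic, rate-based prediction of how interaction strength
responds to temperature.

## The model

Unimodal rates follow the high-temperature-inactivation Sharpe–Schoolfield
thermal performance curve,

```
rate(T) = r_Tref · exp(−Ea/k · (1/T_K − 1/Tref_K))
          / (1 + exp(Eh/k · (1/t_h − 1/T_K)))
```

with activation energy `Ea` (eV), deactivation energy `Eh` (eV),
half-inactivation temperature `t_h` (K), Boltzmann constant
`k = 8.62e−5 eV K⁻¹`, and `T_K = T + 273.15`. The optimum has a closed
form, `Topt_K = Eh·t_h / (Eh + k·t_h·ln(Eh/Ea − 1))`, used both to derive
`Topt`/`MRP` from a fit and, inverted, to rebuild full curves from
published `(Ea, Eh, Topt, MRP)` summaries.

An organism's **energetic balance** is gain/loss on a 0.001 °C prediction
grid: `P/R_r` for an alga, `I^E/R_c^E` for the consumer. `Tm` is the
temperature maximising the balance, `Tc` the crossover where it falls
through 1. Between an interacting pair, mismatch **region 1** is where the
two balances trend in opposite directions and **region 2** where both
decline. The **CREB**, `ln(EB_consumer / EB_resource)`, is classified as
declining / increasing / U-shaped / hump-shaped / flat, which predicts the
trend of per-capita interaction strength — measured from grazing assays as
the Dynamic Index `IS = ln(N/D)/(y·t)`.

Model fitting is exposed as scikit-learn-style estimators
(`SharpeSchoolfieldRegressor`, `TemperatureLinearModel`: `fit`/`predict`,
`get_params`, fitted attributes with trailing underscores), so they compose
with sklearn pipelines; `fit_tpc`, `fit_linear_rate`, `bootstrap_cis` and
`predict_grid` are thin wrappers. Confidence intervals come from a
case-resampling bootstrap.

## Worked example

```python
from thermomatch import fit_tpc, load_preset, generate_rate_samples
from thermomatch.reports import reconstruction_report

# fit a TPC to synthetic net-photosynthesis rates (8 temperatures, n = 6,
# 10% multiplicative noise) drawn from the Chlamydomonas scenario preset
preset = load_preset("chlamydomonas")
rates = generate_rate_samples(preset, "net_photosynthesis",
                              n_per_temp=6, cv=0.1, seed=1)
fit = fit_tpc(rates, tref=20.0, seed=1)
print(f"Ea = {fit.ea_:.3f} eV   Eh = {fit.eh_:.2f} eV   "
      f"Topt = {fit.topt_:.2f} C   MRP = {fit.mrp_:.3g}")

# deterministic mismatch report rebuilt from published curve summaries
report = reconstruction_report("daphnia_on_chlamydomonas")
res = report["resource"]["chlamydomonas"]
print(f"resource Tm = {res['Tm_C']:.3f} C   Tc = {res['Tc_C']:.3f} C")
print(f"consumer Tc = {report['consumer']['Tc_C']:.3f} C")
print(f"CREB trend = {report['creb_trend']}   "
      f"predicted IS trend = {report['predicted_is_trend']}")
```

prints

```
Ea = 1.296 eV   Eh = 5.69 eV   Topt = 32.11 C   MRP = 1.27e-06
resource Tm = 30.686 C   Tc = 37.029 C
consumer Tc = 20.700 C
CREB trend = declining   predicted IS trend = decreasing
```

The fitted slopes sit near the generating summary (`Ea = 1.44 eV`,
`Topt = 31.66 °C`) with single-seed noise; the reconstruction says the
alga's balance peaks at 30.7 °C and turns to net deficit at 37.0 °C, while
the grazer is already in deficit above 20.7 °C — so warming squeezes the
consumer first and its top-down effect should weaken.

The same analysis is available from a shell:

```sh
thermomatch simulate --preset chlamydomonas --seed 1 --out sim/
thermomatch rates --in sim/ --out rates.csv
thermomatch fit --rates rates.csv --model tpc --boot 999 --seed 1 --out fits.json
thermomatch mismatch --pair daphnia_on_chlamydomonas --out reports/
thermomatch run-all --seed 1 --out full_run/
```

## Layout

- `src/thermomatch/tpc.py` — the TPC equation and closed forms
- `src/thermomatch/rates.py` — raw measurements → per-capita rates
- `src/thermomatch/models.py` — estimators, bootstrap, prediction grids
- `src/thermomatch/mismatch.py` — balances, Tm/Tc, regions, CREB, trends
- `src/thermomatch/interaction.py` — Dynamic Index and its GLM
- `src/thermomatch/synth.py` + `presets/` — seeded synthetic-assay generators
- `src/thermomatch/reports.py`, `pipeline.py`, `cli.py`, `io.py` — glue
- `docs/methods.md` — the methods note (assumptions, defaults, limitations)
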