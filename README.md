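# cbcflux

Kinetic analysis of ¹³CO₂-labeling experiments on photosynthetic leaves:
why do Calvin–Benson cycle (CBC) intermediates stop short of full ¹³C
labeling, and why do fully unlabeled (M0) molecules outnumber singly
labeled (M1) ones hours into the chase?

`cbcflux` is for plant metabolic-flux and isotope-labeling researchers.
It provides, in one tested package:

- **Polyexponential washout modelling** — fit
  `u(t) = Σ Aᵢ e^(−kᵢt) (+ C)` to %¹²C decay curves and select the number
  of kinetic components by extra-sum-of-squares F tests (Bonferroni–Holm
  corrected), AIC, BIC, and cross-validation.  A first-order metabolic
  network with M pools produces an M-term polyexponential, so the
  selected K counts the carbon reservoirs feeding the cycle.
- **INST-MFA forward simulation** — EMU-based simulation of mass
  isotopologue distributions over a compartmentalized, atom-mapped
  network of the CBC, photorespiration, sucrose/starch synthesis, the
  cytosolic G6P shunt (G6P → Ru5P + CO₂) and vacuolar sugar pools, with
  closed-form and brute-force isotopomer oracles.
- **Hypothesis-variant flux fitting** — statsmodels-style
  `LabelingFluxModel(...).fit()` returning a results object with the
  fitted flux map, weighted SSR, per-metabolite misfit breakdown, profile
  likelihood and Monte Carlo confidence intervals; `compare_variants`
  ranks alternative unlabeled-carbon-entry mechanisms.
- **Isotopologue diagnostics** — the M0/M1 anomaly: under single-
  population binomial labeling M1/M0 = n·p/(1−p) (≈ 144 for a hexose at
  96 % enrichment); observed ratios far below that flag an intact
  unlabeled subpopulation.
- **Synthetic experiments** — ground-truth-known scenarios emulating the
  study design (14 sampling times over 0–120 min, channel-level MID
  noise), so every stage is testable end to end.

## Worked example

Generate the final-model scenario (carboxylation 172, photorespired CO₂
25, shunt CO₂ 7, glucose entry 1.9 µmol gFW⁻¹ h⁻¹), check its carbon
accounting, and refit the entry flux from the simulated data:

```python
import cbcflux as cf
from cbcflux.synthetic import scenario, generate_dataset

sc = scenario("final_v5", noise_sd=0.0)
acc = cf.carbon_accounting(sc.fluxes)
print(f"extra carbons {acc['extra_carbons']:.0f}, "
      f"photorespiration {acc['photoresp_co2_pct_rounded']}%, "
      f"shunt {acc['shunt_co2_pct_rounded']}%, "
      f"ATP/CO2 {acc['atp_per_net_co2']:.2f}")

noisy, clean, truth = generate_dataset(sc, seed=1)
model = cf.LabelingFluxModel(clean, "V5",
                             free=("invertase_c", "vacuole_cycle"))
fit = model.fit(n_starts=6, seed=0)
print(f"recovered glucose entry {fit.entry_flux():.3f} umol/gFW/h")
```

prints

```
extra carbons 110, photorespiration 18%, shunt 5%, ATP/CO2 3.15
recovered glucose entry 1.900 umol/gFW/h
```

i.e. the flux map implies 110 extra carbon atoms (75 photorespiratory +
35 shunt) processed per 172 carboxylations, CO₂ releases of 18 % and 5 %
of net fixation, an ATP cost of 3.15 per net CO₂ — and the glucose entry
flux is identifiable from the labeling data alone.

The washout analysis on the same scenario:

```python
from cbcflux.synthetic import aggregate_replicates
from cbcflux.polyexp import select_model

t, u = aggregate_replicates(scenario("final_v5"), seed=3000)
report = select_model(t, u, seed=0, n_starts=20)
print(report.winners, report.consensus)
```

selects the triexponential without a constant — three kinetic reservoirs
(CBC, cytosolic sugars, vacuolar sugars) and no metabolically inactive
pool.

A command-line interface mirrors the library:

```sh
cbcflux generate --scenario final_v5 --seed 7 --out-dir run/
cbcflux select-model --data run/aggregate_12c.csv --seed 0
cbcflux fit-flux --data run/mids.csv --variant V5 --starts 20 --seed 1
cbcflux compare --data run/mids.csv --seed 1
cbcflux diagnose --data run/mids.csv --time 60
```

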