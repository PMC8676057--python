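# markovcea

Markov cohort cost-effectiveness analysis of intravitreal anti-VEGF therapy
(conbercept vs. ranibizumab) for age-related macular degeneration (AMD),
diabetic macular edema (DME) and pathological myopia (PM), from a Chinese
payer perspective.

The package models annual cycles over best-corrected visual acuity (BCVA)
bands: the cohort's baseline acuity distribution is propagated through a
row-stochastic annual transition matrix derived from per-drug letter-change
probabilities, accumulating discounted costs (unit price x injections per
year) and QALYs (occupancy-weighted utilities) over a 10-year horizon at a
3.5% discount rate. On top of the cohort engine it provides:

- **CEA statistics** — CER, incremental cost/effect, ICER, dominance
  classification and willingness-to-pay (WTP) decisions routed through net
  monetary benefit (a negative ICER alone is ambiguous).
- **Deterministic sensitivity** — one-way/two-way sweeps over unit prices
  (including ±5%/±10% fluctuations and the 2020 negotiated-price preset)
  and injection counts.
- **Probabilistic sensitivity** — gamma-distributed cost draws (mean equal
  to the deterministic total, configurable coefficient of variation) with
  cost-effectiveness acceptability curves (CEAC).
- **Scenario library** — six built-in scenarios (3 diseases x
  {real_world, rct} injection counts) with all published parameters, plus
  YAML configs layered over the built-ins.
- **Synthetic scenarios** — random but structurally valid parameter sets
  for property testing, with a closed-form QALY oracle.

## CLI

```sh
markovcea list-scenarios
markovcea run --disease AMD --mode real_world --out report.csv
markovcea run --disease PM --negotiated-prices
markovcea sweep --disease DME --parameter unit_price_a \
    --fluctuations -0.1,-0.05,0,0.05,0.1 --out sweep.csv
markovcea sweep --disease AMD --parameter injections_a --values 4.8,5.4,5.8 \
    --parameter2 injections_b --values2 5.4,6.2
markovcea psa --disease PM --iterations 10000 --seed 1 --cost-cv 0.2 \
    --out ceac.csv --plot-prefix pm
markovcea generate --seed 7 --out scenario.yaml
markovcea validate --config scenario.yaml
markovcea run --config scenario.yaml
```

A config may name a built-in disease and override only some keys:

```yaml
disease: AMD
mode: real_world
arms:
  a:
    unit_price: 4160.0
```

Exit codes: 0 success, 2 validation/parameter error, 3 I/O error.

## Python API

```python
import markovcea as mc

scenario = mc.load_builtin("DME", "real_world")
result = mc.run_base_case(scenario)
print(result.comparison.icer, result.comparison.dominance)

psa = mc.run_psa(scenario, mc.PSAConfig(iterations=10_000, seed=1, cost_cv=0.2))
print(psa.ceac.head())
```

## Modelling conventions

Documented toggles (defaults in parentheses): boundary folding of
out-of-ladder shifts into the nearest feasible state with recovery from
blindness allowed (`blindness_absorbing` off), no half-cycle correction
(`half_cycle_correction` off), first cycle undiscounted / annuity-due
(`first_cycle_discounted` off). Only costs are randomized in the PSA;
utilities and transitions are held at their point estimates.
`other_annual_cost` defaults to 0 — published cost totals include non-drug
components that are not itemized, so drug-only totals are lower than the
published ones; users can calibrate via this parameter.
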