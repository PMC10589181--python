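# litterfate

Carbon added to soil as plant litter is either respired, retained as
particulate organic carbon (POC), or stabilised as mineral-associated
organic carbon (MAOC) — and fresh litter can *prime* the decomposition of
native soil carbon. `litterfate` is a Python package for analysing
two-pool, two-source soil incubation experiments that trace these fluxes
with natural-abundance stable isotopes: a C4 grass litter (δ¹³C ≈ −14‰)
added to a C3-dominated soil (δ¹³C ≈ −26‰), size-fractionated at a 20 µm
cut into coarse (POC) and fine (MAOC) fractions.

It is written for soil biogeochemists who want a tested, reproducible
version of the standard accounting chain — and a synthetic-data generator
that emulates the whole jar experiment, so every stage can be validated
without laboratory data.

## The model

The litter-derived ("new") carbon fraction of any sample follows from the
linear two-source mixing equation

```
f_C4 = (δ¹³C_sample − δ¹³C_reference) / (δ¹³C_litter − δ¹³C_reference)
```

with per-fraction reference signatures taken from the unamended control at
the start of the incubation (the POC reference sits ≈ 0.5‰ below the MAOC
reference). Applied to the coarse and fine fraction carbon contents
(converted to a whole-soil basis with constant per-treatment mass
proportions), this yields four pools — POC_new, POC_old, MAOC_new,
MAOC_old — plus recovery diagnostics. On top of the pools the package
computes:

- **litter-C fate**: % of added litter C remaining as POC, transformed to
  MAOC, or respired (the mass-balance residual);
- **litter-N mineralisation**: lost litter C divided by the litter C:N;
- **priming**: relative difference in old-C loss versus the control;
- **DRIFT litter-quality indices**: maximum-absorbance band ratios
  (aliphatic/aromatic, polysaccharide/lignin, aliphatic/amide I–III);
- **statistics**: per-occasion OLS of each pool on litter quality, and
  one-way ANOVA with Tukey HSD compact letters.

The synthetic generator integrates a linear four-pool system exactly
(first-order decay, POC→MAOC transfer preserving source identity, and a
C:N-dependent priming multiplier on the native pools) and adds a
realistic measurement layer (δ¹³C SD 0.2‰, 3% concentration CV, 98.2 ±
0.7% fractionation mass recovery).

## Worked example

```python
import litterfate as lf

ds = lf.generate_experiment()                      # default design, seed 0
res = lf.analyze_experiment(ds.observations, ds.design)

avg = res.relative_changes[res.relative_changes["treatment"] == "Average"].iloc[0]
print(f"mean SOC change after 24 months: {avg['d_soc_mean']:.1f}% "
      f"(SD {avg['d_soc_sd']:.1f})")
fate = res.litter_fate.query("month == 24").mean(numeric_only=True)
print(f"added litter C after 24 months: {fate['pct_remaining_poc']:.0f}% POC, "
      f"{fate['pct_maoc']:.0f}% MAOC, {fate['pct_respired']:.0f}% respired")
row = res.regressions.query("pool == 'maoc_old' and month == 24").iloc[0]
print(f"MAOC_old ~ litter C:N at 24 mo: slope {row['slope']:.4f}, "
      f"R2 {row['r_squared']:.2f}, p {row['p_value']:.4f}")
print("Tukey letters (bulk SOC, 24 mo):", res.tukey["bulk_total"].letters)
```

prints

```
mean SOC change after 24 months: -46.8% (SD 2.2)
added litter C after 24 months: 20% POC, 10% MAOC, 71% respired
MAOC_old ~ litter C:N at 24 mo: slope -0.0032, R2 0.15, p 0.0969
Tukey letters (bulk SOC, 24 mo): {'CN50': 'a', 'CN65': 'ab', 'CN85': 'ab', 'CN124': 'ab', 'CN124N': 'b'}
```

Read: this simulated experiment lost about half of its total organic C in
two years; of the added litter C roughly 70% was respired, 20% persisted
as particulate C and 10% was stabilised on minerals. The native MAOC pool
declines with litter C:N (negative slope, g C kg⁻¹ per C:N unit), though
in this noisy single realisation the 24-month regression misses the 5%
significance level; the letter display separates the lowest-C:N treatment
from the N-amended high-C:N treatment.

The same pipeline runs from the shell:

```
litterfate generate --seed 0 --out data/
litterfate analyze data/observations.csv --config data/run_config.yaml --out results/
litterfate report data/observations.csv
```

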