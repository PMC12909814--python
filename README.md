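# cobenefits

Source–receptor attribution of PM2.5 climate co-benefits and the
transboundary inequality metrics built on it.

## The problem

Climate mitigation cuts emissions of PM2.5 precursors (BC, OC, NH₃, NOₓ,
SO₂) alongside greenhouse gases, avoiding premature deaths — "co-benefits".
Because fine particulate matter crosses borders, part of each country's
co-benefits originates from *other* countries' action. This package is for
air-quality and health-impact modellers who have (or want to emulate)
linearized source–receptor sensitivities from a chemical transport model
and want to quantify, per country and scenario:

1. how gridded emission changes translate into population-weighted PM2.5
   exposure changes,
2. how exposure changes translate into avoided deaths, and
3. how unequally those co-benefits are exchanged across borders.

## The model

For receptor country *m*, precursor species *k* and grid cell *I*, an
adjoint-style sensitivity λ_{I,k,m} = ∂J_m/∂E_{I,k} (µg m⁻³ per Tg yr⁻¹)
relates the country's population-weighted exposure J_m to emissions. Given
scenario-minus-baseline emission deltas ΔE_{I,k,s}, the per-cell exposure
contribution is

    ΔJ_{I,m,s} = Σ_k λ_{I,k,m} · ΔE_{I,k,s}

Avoided deaths use the GBD attributable-fraction form per outcome and age
group, Mortality = y0 · (1 − 1/RR(z)) · Pop, evaluated twice per source
cell — at the baseline exposure J_m and at J_m + ΔJ_{I,m,s} — and
differenced, then aggregated over outcomes and ages, with lower/central/
upper uncertainty passes.

Three inequality metrics summarize the result:

- **TF** (transboundary fraction): Σ_{I∉m} ΔJ_{I,m,s} / Σ_I ΔJ_{I,m,s},
  the share of a receptor's co-benefits from outside its territory
  (computed on deaths avoided by default);
- **EXC**(m, n) = Σ_{I∈m} ΔJ_{I,n,s}: co-benefits in n from action in m,
  with the pairwise net exchange EXC(m,n) − EXC(n,m);
- **TEC**(m, n) = EXC(m,n) / (EXC(m,n) + EXC(n,m)): m's share of the
  gross co-benefits a pair exchanges (0.5 = balance).

Real sensitivity fields are cluster-scale model products, so the package
ships a synthetic-world generator (grid, contiguous countries, westerly-
skewed Gaussian sensitivity kernels, scenario inventories, GBD-like health
tables) with planted ground truth for end-to-end verification. See
`docs/methods.md` for assumptions and numerical choices.

## Worked example

```python
import cobenefits as cb

world = cb.generate_world(cb.WorldConfig(seed=1))
scenarios = cb.generate_scenarios(
    world.grid, world.masks, world.config,
    [cb.ScenarioSpec("baseline"), cb.ScenarioSpec("strong", 0.60)],
)
delta = cb.scenario_delta(scenarios[1], scenarios[0])
dj = cb.attribute_exposure(world.sensitivities, delta)
deaths = cb.deaths_avoided(dj, world.baseline_exposure, world.risk_model)
matrix = cb.aggregate_sources(deaths, world.masks, quantity="deaths")
report = cb.build_report(deaths, matrix, world.masks)

print(report.summary().to_string())
print(report.tf[["total", "domestic", "external", "tf"]].head().round(2))
print("TEC(C00, C01) =", round(cb.tec(matrix, "C00", "C01")[0], 3))
```

prints

```
scenario                      strong
bound                        central
total_deaths_avoided    15251.509775
global_tf                   0.741735
mean_country_tf             0.773115

            total  domestic  external    tf
receptor
C00       2028.23    602.68   1425.55  0.70
C01       1365.88    193.63   1172.24  0.86
C02        539.10    116.33    422.77  0.78
C03        688.96    149.86    539.10  0.78
C04       1692.08    587.18   1104.90  0.65

TEC(C00, C01) = 0.182
```

A 60% uniform emission cut on this ten-country world avoids ~15,250 deaths
per year relative to the no-mitigation baseline. The `tf` column shows
each receptor's transboundary fraction (C01 receives 86% of its co-benefits
from abroad); the TEC value says C00 contributes only 18% of the gross
co-benefits the C00–C01 pair exchanges, so C01 dominates that exchange.

The same chain is scriptable from the shell:

```sh
cobenefits run --seed 1 --out demo_run   # world → delta → attribute → health → metrics
cobenefits metrics strata --tf demo_run/tf_strong_central.csv \
    --country-table demo_run/countries.csv -k 3 --out strata.csv
```

`cobenefits run` writes `tf_*.csv`, `exc_*.csv`, `strata_*.csv`,
`summary.csv`, `comparison.csv` and a `manifest.json` with a checksum of
every output; rerunning the same config reproduces identical checksums.

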