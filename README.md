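# foodsys

A national food-and-land-use scenario calculator for food-security
analysis, built for countries — The Gambia is the packaged example — whose
rapidly growing food demand must be met from some mix of low-productivity
domestic agriculture, imports and cropland expansion. It is an accounting
model (no prices, no optimisation) on a five-year grid from 2000 to 2050,
aimed at analysts who want transparent, reproducible supply–demand
arithmetic under scenario assumptions rather than a market equilibrium.

## Model

Historical commodity balance sheets over a calibration window (2000–2010)
are reduced to a baseline: per-capita food supply `s_c` (fixed diet),
import share `m_c` of domestic supply, export volumes `E_c`, and non-food
utilisation shares (feed, seed, waste, other) `u_c`. For a population
scenario `P(t)`:

- **demand**: `D_c(t) = s_c · P(t)`; domestic-supply target
  `S_c(t) = D_c(t) / (1 − u_c)`; import target `m_c · S_c(t)`; production
  target `S_c(t)(1 − m_c) + E_c`.
- **feasible production** on fixed cropland:
  `Q_c(t) = A_c · y_c · f_c(t)` where the yield shifter `f_c(t)` composes
  multiplicatively from (i) an RCP-derived climate series (CO₂
  fertilisation on/off as an uncertainty band), (ii) a climate-change
  adaptation (CCA) gain of 13% on the six focus crops (rice, millet,
  maize, sorghum, groundnut, cassava) scaled by an adoption schedule, and
  (iii) an intensification ("Boost") ramp rising linearly to a 2050
  target yield of 75% of the crop's yield potential (or the historical
  maximum, if higher).
- **gap**: `G_c(t) = max(0, target_c(t) − Q_c(t))`, with shares relative
  to the production target; calorie availability
  `Σ_c food_c(t)·k_c / P(t) / 365` falls below the baseline diet when
  gaps open, because imports keep their *share* rather than filling
  shortfalls.
- **land**: the cultivated area needed to meet targets with imports
  frozen at baseline volumes, truncated by a national land-area cap;
  crop GHG emissions as `Σ_c A_c·ef_area,c + Q_c·ef_product,c`.

All inputs are synthetic: a deterministic "Gambia-like" fixture
(350,000 ha harvested area, 2553 kcal/cap/day baseline diet, 83% rice
import share, 2.8%/yr baseline population growth) plus seeded generators
for noisy balance sheets, population scenarios and climate shifters.

## Worked example

```python
from foodsys import PathwayConfig, run_pathway

bau = run_pathway(PathwayConfig(management="BAU"))        # SSP2, RCP2.6
both = run_pathway(PathwayConfig(management="CCA_BOOST"))
print(f"2050 BAU gap: {bau.gaps.totals.loc[2050, 'gap']:,.0f} t "
      f"({100 * bau.gaps.gap_share_at(2050):.0f}%)")
print(f"2050 CCA&Boost gap: {both.gaps.totals.loc[2050, 'gap']:,.0f} t "
      f"({100 * both.gaps.gap_share_at(2050):.0f}%)")
```

prints

```
2050 BAU gap: 915,339 t (70%)
2050 CCA&Boost gap: 446,156 t (34%)
```

i.e. under business-as-usual management the fixture country can feasibly
produce only ~30% of its 2050 production target, and combining adaptation
with intensification roughly halves the missing supply (the remaining gap
is 49% of the BAU gap). The numbered drivers under `analysis/` walk the
full study: `01` writes the inputs, `02` projects demand and its
population-scenario envelope, `03` compares feasible production across
management and climate scenarios (CO₂ bands 1–5% under RCP2.6 and 2–8%
under RCP6.0 in 2050), `04` quantifies gaps, scenario deltas and calorie
deficits, `05` computes cropland-expansion requirements against the land
cap and crop GHG emissions. Each writes tidy CSVs under `results/`.

A CLI wraps the same pipeline: `foodsys run --config pathway.yaml --out
DIR`, `foodsys grid --configs DIR`, `foodsys synth --seed N --out DIR`.

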