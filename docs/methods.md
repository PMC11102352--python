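# Methods

## Model structure and assumptions

The calculator is a deterministic accounting model on a five-year grid
(2000–2050, projections from 2015). It deliberately excludes prices,
market feedbacks, diet change, biofuels and livestock-productivity
scenarios: demand is driven by population alone under a fixed diet, and
supply by yield shifters on fixed cropland. This isolates the question
the tool is built for — whether productivity gains can close a growing
supply–demand gap — at the cost of ignoring demand-side adjustment.

Calibration reduces yearly balance sheets over 2000–2010 to arithmetic
means per commodity and element (the window's statistic is a plain mean;
nothing in the inputs justifies anything fancier). Population is defined
on the five-year grid, so its calibration mean is taken over the grid
points inside the window (2000, 2005, 2010). Stock-variation and
statistical-discrepancy elements are accepted on input but excluded from
the supply identity `supply = production + imports − exports`.
Commodities with zero domestic supply are kept with zero demand and
import share 0, keeping all ledgers rectangular. Downstream stages see
only the calibrated `Baseline` — never the raw calibration records.

Fixed factors follow the wording of their sources: food waste, feed and
seed are *shares* of domestic supply (they scale with it), while exports
and — in the land counterfactual — imports are absolute *volumes*. The
import share is the constant that links feasible production to feasible
supply: `S = (Q − E)/(1 − m)`. For `m = 1` (fully import-dependent
commodities such as the fixture's wheat) that formula is vacuous, so
feasible supply follows the demand-side target when a demand ledger is
available and baseline import volumes otherwise; the production target
degenerates to the export volume. This choice preserves the closure
property that forcing feasible production onto the targets reproduces
food demand, and hence the baseline calorie level, exactly.

## Shifters

Climate series are multiplicative, piecewise-linear in time, equal to 1
at 2015, with 2050 endpoints per climate scenario and a CO₂-fertilisation
on/off pair whose spread is reported as an uncertainty band (on ≥ off by
construction). Sorghum always carries the millet series — the two crops
are biophysically similar and no separate projections exist.

CCA applies `1 + g·a(t)` on the six focus crops with `g = 0.13`
(a pooled mean effect of adaptation practice studies in the region;
uniform across crops, with a per-crop override table for users with
better information) and an adoption schedule `a(t)` ramping linearly
from 0 in 2020 to 1 in 2030. The early saturation is intentional:
adaptation is a near-term management change, which is why its production
effect barely grows between 2030 and 2050.

Boost targets `max(0.75 · yield_potential, yield_hist_max)` in 2050,
never below the current yield, reached by a straight line in yield space
from 2020 sampled at the grid points; the multiplier therefore hits
`target/yield_base` at 2050 with no interpolation drift. Ramp start 2020
(the first projection point after the calibration-anchored 2015) is a
package default, configurable.

Shifters compose by pointwise multiplication — order-independent, and
the combined scenario exceeds the sum of its parts, which is the model's
explanation for the super-additive combined production effect.

## Gap, calories, land, GHG

Gaps are `max(0, target − feasible)` per commodity-year; shares use the
production target as denominator, consistently, and aggregate as sums.
Imports do not respond to shortfalls (constant share, not gap-filling —
a gap-filling mode exists, off by default), so gaps propagate to calorie
availability at 365 days/yr. The land counterfactual instead freezes
imports at baseline volumes and asks what area each scenario's yields
would require; a single national land-area cap truncates the answer and
reports the residual, standing in for the full land-cover bookkeeping a
larger model would carry. GHG is a linear factor model
(`area · ef_area + production · ef_product`); the shipped factors are
synthetic placeholders (rice carries a higher area factor for paddy
methane) because no emission method accompanies the study context — the
resulting magnitudes are illustrative only and are not asserted anywhere.

## Synthetic inputs and the fixture

The generators emulate the *structure* of the real inputs, not their
values: lognormal multiplicative yearly noise (default CV 0.05,
mean-one) on calibration quantities keeps positivity and lets a CV-0 run
recover the generating means exactly (tested to 1e-9); population
scenarios compound annual growth with an optional per-decade decline,
the baseline at 2.8%/yr constant; climate series are linear ramps as
above. Everything is reproducible from a single seed via independent
per-component streams (CRC-keyed `SeedSequence` spawns).

The packaged fixture is calibrated in aggregate only: harvested area
sums to 350,000 ha; the calibration-mean population is *solved* from the
energy total so the baseline diet supplies exactly 2553 kcal/cap/day;
rice has an 83% import share; climate endpoints give central crop
production declines of 3% (low-emission scenario) and 5% (mid-high) in
2050. Yield potentials sit at 2–3.5× current yields — chosen once, at
design time, as a realistic magnitude for the region's attainable yield
gaps and such that combining adaptation and intensification roughly
halves the business-as-usual 2050 gap. Per-crop splits, energy contents
and emission factors are plausible placeholders, not observed records.

What passing tests on this fixture do **not** show: the fixture's
constant 2.8%/yr growth overshoots realistic mid-century demand (real
demographic scenarios decelerate), so absolute gap sizes, calorie
deficits and expansion percentages are larger than a real-data
application would produce; only the relational structure (scenario
ordering, band widths, halving ratio, identities) is meaningful.

## Numerical choices

Tonnes, hectares and persons internally; kg/capita and kcal/cap/day only
at reporting boundaries (default rounding: nearest percent, nearest
thousand tonnes). Demand exists only on grid points — no sub-period
interpolation. Negative intermediate quantities (exports exceeding
production plus imports, targets driven negative) are clipped to zero
with warnings rather than erroring, since they arise from legitimately
extreme scenario inputs. The Boost boundary tie (historical maximum
exactly at 75% of potential) resolves to the same value either way.
Supply identities are enforced to 1e-6 relative in validation and hold
to ~1e-12 in practice. Exports are byte-identical across runs for a
fixed config and seed; the run manifest carries a config hash and no
timestamps for that reason.

Problem sizes throughout (10 commodities, 8 projection years, 11
calibration years) make every pathway run a few milliseconds, so the
full scenario grid, the property suites and the analysis drivers all run
in seconds.

## Known limitations

No prices or trade elasticities; no diet shifts (the dominant source of
real demand uncertainty after population); no sub-national structure; no
extreme-event yield variability (shifters are smooth trends); a single
land cap instead of land-cover dynamics; energy-only nutrition (no
protein or micronutrients). The GHG module is a placeholder-factor
accounting, suitable for sensitivity exploration only.
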