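"""Synthetic inputs with the statistical structure the analysis assumes.

Real applications of the calculator ingest national food-balance sheets,
demographic-scenario population tables and process-model climate yield
shifters. None of those are redistributable here, so this module
generates structurally faithful stand-ins:

* balance sheets -- yearly 2000-2010 records per commodity, lognormal
  multiplicative noise around commodity means, supply identities enforced
  by construction;
* population -- five demographic-scenario analogues on the five-year
  grid, the baseline compounding at 2.8 %/yr with an optional per-decade
  rate decline;
* climate shifters -- piecewise-linear multipliers from 1.0 at the first
  projection year to scenario-specific 2050 endpoints, with a CO2
  fertilisation on/off band (on >= off) and the sorghum <- millet mapping;
* ``gambia_fixture`` -- a deterministic, noise-free bundle calibrated so
  the headline baseline quantities (350,000 ha harvested area, 2553
  kcal/cap/day) hold exactly. All other fixture values are plausible
  placeholders, not observed national data.

Every output is fully determined by the generator seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    Baseline,
    BalanceSheet,
    CropParams,
    NONFOOD_USES,
    TimeGrid,
)
from .demand import PopulationTrajectory, SSP_SCENARIOS
from .yields import ClimateShifter, FOCUS_CROPS, RCPS

__all__ = [
    "GeneratorSpec",
    "generate_balance_sheets",
    "generate_population",
    "generate_climate_shifters",
    "generate_crop_params",
    "baseline_to_balance_sheet",
    "gambia_fixture",
    "FixtureBundle",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters controlling the synthetic input generator.

    noise_cv is the coefficient of variation of the lognormal yearly
    noise on calibration quantities (0 gives constant records). Growth
    rates are fractions per year; rate_decline is subtracted per decade.
    Climate endpoints are 2050 multipliers by scenario (CO2 on / off).
    """

    seed: int = 0
    n_commodities: int = 6
    noise_cv: float = 0.05
    growth_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "SSP1": 0.020,
            "SSP2": 0.028,
            "SSP3": 0.034,
            "SSP4": 0.024,
            "SSP5": 0.031,
        }
    )
    rate_decline_per_decade: float = 0.0
    climate_endpoints: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # 2050 multipliers (CO2 on, CO2 off): central -3% / -5%,
            # bands -1..-5% and -2..-8%
            "RCP2.6": (0.99, 0.95),
            "RCP6.0": (0.98, 0.92),
        }
    )
    area_range: tuple[float, float] = (5_000.0, 150_000.0)  # ha
    yield_range: tuple[float, float] = (0.8, 3.0)  # t/ha
    potential_ratio_range: tuple[float, float] = (2.0, 3.5)  # potential / base
    population_base: float = 1.8e6  # persons at the grid start

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_commodities < 1:
            raise ValueError("need at least one commodity")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per generator component."""
        key = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


def _commodity_names(n: int) -> list[str]:
    names = list(FOCUS_CROPS)
    extra = [f"commodity_{i}" for i in range(len(names), n)]
    return (names + extra)[:n]


def generate_crop_params(spec: GeneratorSpec) -> dict[str, CropParams]:
    """Random but seed-determined crop parameters for the focus crops."""
    rng = spec.rng("crop_params")
    out: dict[str, CropParams] = {}
    for name in _commodity_names(spec.n_commodities):
        area = rng.uniform(*spec.area_range)
        yld = rng.uniform(*spec.yield_range)
        potential = yld * rng.uniform(*spec.potential_ratio_range)
        hist = yld * rng.uniform(1.05, 1.5)
        out[name] = CropParams(
            commodity=name,
            area_base=area,
            yield_base=yld,
            yield_potential=potential,
            yield_hist_max=hist,
            kcal_per_tonne=rng.uniform(1.0e6, 4.0e6),
            ef_area=rng.uniform(0.1, 1.5),
            ef_product=rng.uniform(0.0, 0.1),
        )
    return out


def generate_balance_sheets(
    spec: GeneratorSpec,
    params: Mapping[str, CropParams] | None = None,
    grid: TimeGrid | None = None,
) -> BalanceSheet:
    """Yearly calibration-window balance sheets with multiplicative noise.

    Commodity means are production = area x yield (or random volumes when
    no crop parameters are given) plus random import/export/non-food
    structure; each yearly record is the mean times a lognormal factor
    with the spec's CV. Supply >= uses holds by construction because the
    utilisation elements are shares of the realised domestic supply.
    """
    grid = grid or TimeGrid()
    params = params if params is not None else generate_crop_params(spec)
    rng = spec.rng("balance")
    sigma = float(np.sqrt(np.log(1.0 + spec.noise_cv**2))) if spec.noise_cv > 0 else 0.0

    def noisy(mean: float) -> float:
        if mean <= 0:
            return 0.0
        if sigma == 0.0:
            return mean
        return mean * float(rng.lognormal(-0.5 * sigma**2, sigma))

    records = []
    for name in _commodity_names(spec.n_commodities):
        if name in params:
            prod_mean = params[name].area_base * params[name].yield_base
        else:
            prod_mean = rng.uniform(1e4, 2e5)
        share = rng.uniform(0.0, 0.6)
        import_mean = prod_mean * share / (1.0 - share)
        export_mean = prod_mean * rng.uniform(0.0, 0.3)
        feed, seed_u, waste = rng.uniform(0.0, 0.08, size=3)
        for year in grid.calibration_years:
            prod = noisy(prod_mean)
            imp = noisy(import_mean)
            exp = min(noisy(export_mean), prod + imp)  # keep supply >= 0
            supply = prod + imp - exp
            uses = {
                "feed": feed * supply,
                "seed": seed_u * supply,
                "waste": waste * supply,
                "other": 0.0,
            }
            food = supply - sum(uses.values())
            for el, v in (
                ("production", prod),
                ("imports", imp),
                ("exports", exp),
                ("food", food),
                *uses.items(),
            ):
                records.append((name, year, el, v))
    return BalanceSheet(pd.DataFrame(records, columns=BalanceSheet.COLUMNS))


def _trajectory(
    scenario: str,
    p0: float,
    rate: float,
    decline_per_decade: float,
    grid: TimeGrid,
) -> PopulationTrajectory:
    values = {}
    pop = p0
    values[grid.start_year] = pop
    years = list(grid.years)
    for prev, year in zip(years, years[1:]):
        for step_year in range(prev, year):
            decades = (step_year - grid.start_year) / 10.0
            r = max(0.0, rate - decline_per_decade * decades)
            pop *= 1.0 + r
        values[year] = pop
    return PopulationTrajectory(scenario=scenario, values=pd.Series(values))


def generate_population(
    spec: GeneratorSpec, grid: TimeGrid | None = None
) -> dict[str, PopulationTrajectory]:
    """Five demographic-scenario analogues on the grid.

    The baseline (SSP2 analogue) compounds at 2.8 %/yr by default; the
    other scenarios bracket it so the 2050 totals span a realistic
    uncertainty range.
    """
    grid = grid or TimeGrid()
    return {
        scn: _trajectory(
            scn,
            spec.population_base,
            spec.growth_rates[scn],
            spec.rate_decline_per_decade,
            grid,
        )
        for scn in SSP_SCENARIOS
    }


def generate_climate_shifters(
    spec: GeneratorSpec,
    crops: list[str] | None = None,
    grid: TimeGrid | None = None,
) -> dict[tuple[str, bool], ClimateShifter]:
    """Piecewise-linear climate multipliers per (scenario, CO2 switch).

    Each series runs from 1.0 at the first projection year to the
    configured 2050 endpoint; the CO2-on series is never below the
    CO2-off series, and sorghum copies the millet series.
    """
    grid = grid or TimeGrid()
    crops = crops if crops is not None else list(FOCUS_CROPS)
    years = list(grid.projection_years)
    span = grid.end_year - grid.projection_start
    out: dict[tuple[str, bool], ClimateShifter] = {}
    for rcp, (end_on, end_off) in spec.climate_endpoints.items():
        if end_on < end_off:
            raise ValueError(f"{rcp}: CO2-on endpoint must be >= CO2-off endpoint")
        for co2, endpoint in ((True, end_on), (False, end_off)):
            frame = pd.DataFrame(
                {
                    y: 1.0 + (endpoint - 1.0) * (y - grid.projection_start) / span
                    for y in years
                },
                index=pd.Index(crops, name="crop"),
            )
            frame = ClimateShifter.enforce_sorghum_mapping(frame)
            out[(rcp, co2)] = ClimateShifter(
                rcp=rcp, co2_fertilisation=co2, values=frame
            )
    return out


def baseline_to_balance_sheet(
    base: Baseline,
    population: Mapping[int, float],
    years: list[int] | None = None,
    grid: TimeGrid | None = None,
) -> BalanceSheet:
    """Regenerate a (noise-free) balance sheet implied by a Baseline.

    Useful for the calibration-idempotence check: calibrating the
    regenerated sheet at the same population returns the same Baseline.
    """
    grid = grid or TimeGrid()
    years = years if years is not None else list(grid.calibration_years)
    pop = pd.Series(dict(population)).astype(float)
    records = []
    for c in base.commodities:
        share = float(base.import_share[c])
        exports = float(base.exports_base[c])
        nonfood = base.nonfood_factors.loc[c]
        food_share = 1.0 - float(nonfood.sum())
        for y in years:
            p = float(pop.get(y, base.population_base))
            food = float(base.per_capita_supply[c]) * p
            supply = food / food_share if food_share > 0 else 0.0
            imports = share * supply if share < 1.0 - 1e-9 else supply + exports
            production = supply - imports + exports
            rows = {
                "production": max(0.0, production),
                "imports": imports,
                "exports": exports,
                "food": food,
                **{u: float(nonfood[u]) * supply for u in NONFOOD_USES},
            }
            for el, v in rows.items():
                records.append((c, y, el, v))
    return BalanceSheet(pd.DataFrame(records, columns=BalanceSheet.COLUMNS))


# --------------------------------------------------------------------------
# Deterministic Gambia-like fixture
# --------------------------------------------------------------------------

#: Per-crop fixture table: area (ha), base yield, yield potential,
#: historical max (t/ha), kcal/t, import share, exports (t), non-food
#: shares, emission factors. Areas sum to 350,000 ha. SYNTHETIC
#: placeholders calibrated only in aggregate -- not observed records.
_FIXTURE_CROPS: dict[str, dict] = {
    "millet": dict(area=130_000, yld=1.0, pot=2.6, hist=1.3, kcal=3.4e6,
                   share=0.02, exports=0.0, feed=0.05, seed=0.03, waste=0.10,
                   ef_area=0.35, ef_product=0.02),
    "groundnut": dict(area=120_000, yld=0.9, pot=2.5, hist=1.2, kcal=5.67e6,
                      share=0.0, exports=40_000.0, feed=0.0, seed=0.03,
                      waste=0.10, ef_area=0.30, ef_product=0.02),
    "rice": dict(area=55_000, yld=0.8, pot=3.2, hist=1.2, kcal=3.6e6,
                 share=0.83, exports=0.0, feed=0.0, seed=0.03, waste=0.10,
                 ef_area=1.20, ef_product=0.05),
    "maize": dict(area=25_000, yld=1.2, pot=3.5, hist=1.6, kcal=3.65e6,
                  share=0.15, exports=0.0, feed=0.10, seed=0.03, waste=0.10,
                  ef_area=0.35, ef_product=0.02),
    "sorghum": dict(area=15_000, yld=0.9, pot=2.4, hist=1.1, kcal=3.4e6,
                    share=0.02, exports=0.0, feed=0.05, seed=0.03, waste=0.10,
                    ef_area=0.35, ef_product=0.02),
    "cassava": dict(area=5_000, yld=3.0, pot=7.0, hist=4.0, kcal=1.1e6,
                    share=0.0, exports=0.0, feed=0.0, seed=0.03, waste=0.10,
                    ef_area=0.25, ef_product=0.01),
}

#: Non-crop commodities: frozen production, import-driven supply.
_FIXTURE_OTHER: dict[str, dict] = {
    "wheat": dict(prod=0.0, share=1.0, imports=60_000.0, exports=0.0,
                  kcal=3.4e6, feed=0.0, seed=0.0, waste=0.10),
    "milk": dict(prod=10_000.0, share=0.70, imports=None, exports=0.0,
                 kcal=0.6e6, feed=0.0, seed=0.0, waste=0.10),
    "fish": dict(prod=40_000.0, share=0.10, imports=None, exports=0.0,
                 kcal=0.8e6, feed=0.0, seed=0.0, waste=0.10),
    "vegetables": dict(prod=20_000.0, share=0.20, imports=None, exports=0.0,
                       kcal=0.25e6, feed=0.0, seed=0.0, waste=0.10),
}

#: Headline calibration targets for the fixture.
FIXTURE_AREA_TOTAL = 350_000.0  # ha
FIXTURE_KCAL_BASELINE = 2553.0  # kcal/cap/day
FIXTURE_LAND_CAP = 1_000_000.0  # ha, national land area analogue
FIXTURE_GROWTH_RATE = 0.028  # /yr, baseline scenario


@dataclass
class FixtureBundle:
    """Complete deterministic input bundle for the packaged fixture."""

    balance_sheet: BalanceSheet
    crop_params: dict[str, CropParams]
    populations: dict[str, PopulationTrajectory]
    climate: dict[tuple[str, bool], ClimateShifter]
    kcal_per_tonne: dict[str, float]
    land_cap: float
    grid: TimeGrid


def _fixture_supply_table() -> pd.DataFrame:
    """Constant-year supply/utilisation table implied by the fixture crops."""
    rows = {}
    for name, d in _FIXTURE_CROPS.items():
        prod = d["area"] * d["yld"]
        share = d["share"]
        supply = (prod - d["exports"]) / (1.0 - share)
        imports = share * supply
        rows[name] = dict(production=prod, imports=imports, exports=d["exports"],
                          supply=supply, feed=d["feed"], seed=d["seed"],
                          waste=d["waste"], kcal=d["kcal"])
    for name, d in _FIXTURE_OTHER.items():
        share = d["share"]
        if share >= 1.0 - 1e-9:
            imports = d["imports"]
            supply = d["prod"] + imports - d["exports"]
        else:
            supply = (d["prod"] - d["exports"]) / (1.0 - share)
            imports = share * supply
        rows[name] = dict(production=d["prod"], imports=imports,
                          exports=d["exports"], supply=supply, feed=d["feed"],
                          seed=d["seed"], waste=d["waste"], kcal=d["kcal"])
    df = pd.DataFrame(rows).T
    df["food"] = df["supply"] * (1.0 - df["feed"] - df["seed"] - df["waste"])
    return df


def gambia_fixture(grid: TimeGrid | None = None) -> FixtureBundle:
    """Deterministic Gambia-like input bundle.

    Calibrated so the harvested area totals 350,000 ha and the baseline
    diet supplies exactly 2553 kcal/cap/day (the base population is
    solved from the energy total rather than prescribed). Yield
    potentials sit at 2-3.5x current yields, consistent with the large
    attainable yield gaps reported for the region.
    """
    grid = grid or TimeGrid()
    table = _fixture_supply_table()

    # solve the calibration-mean population from the calorie target
    kcal_total = float((table["food"] * table["kcal"]).sum())  # kcal/yr
    pop_mean = kcal_total / (FIXTURE_KCAL_BASELINE * 365.0)
    cal_grid = grid.calibration_grid_years()
    growth = np.mean([
        (1.0 + FIXTURE_GROWTH_RATE) ** (y - grid.start_year) for y in cal_grid
    ])
    population_base = pop_mean / float(growth)

    spec = GeneratorSpec(
        seed=0,
        n_commodities=len(table),
        noise_cv=0.0,
        population_base=population_base,
    )
    populations = generate_population(spec, grid)

    records = []
    for name, row in table.iterrows():
        for year in grid.calibration_years:
            supply = row["supply"]
            for el, v in (
                ("production", row["production"]),
                ("imports", row["imports"]),
                ("exports", row["exports"]),
                ("food", row["food"]),
                ("feed", row["feed"] * supply),
                ("seed", row["seed"] * supply),
                ("waste", row["waste"] * supply),
                ("other", 0.0),
            ):
                records.append((name, year, el, v))
    bs = BalanceSheet(pd.DataFrame(records, columns=BalanceSheet.COLUMNS))

    crop_params = {
        name: CropParams(
            commodity=name,
            area_base=float(d["area"]),
            yield_base=float(d["yld"]),
            yield_potential=float(d["pot"]),
            yield_hist_max=float(d["hist"]),
            kcal_per_tonne=float(d["kcal"]),
            ef_area=float(d["ef_area"]),
            ef_product=float(d["ef_product"]),
        )
        for name, d in _FIXTURE_CROPS.items()
    }
    assert abs(sum(p.area_base for p in crop_params.values()) - FIXTURE_AREA_TOTAL) < 1e-6

    climate = generate_climate_shifters(spec, crops=list(_FIXTURE_CROPS), grid=grid)
    kcal = {name: float(row["kcal"]) for name, row in table.iterrows()}
    return FixtureBundle(
        balance_sheet=bs,
        crop_params=crop_params,
        populations=populations,
        climate=climate,
        kcal_per_tonne=kcal,
        land_cap=FIXTURE_LAND_CAP,
        grid=grid,
    )
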