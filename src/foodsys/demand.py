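"""Food-demand projection and production/import targets.

Diets are held fixed at the calibration-window per-capita supply, so food
demand scales exactly with population. The domestic-supply target per
commodity is the level whose food share meets that demand after the
calibrated non-food uses (feed, seed, waste, other) are taken out; imports
keep their calibration share of domestic supply and exports stay at their
baseline volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Baseline, TimeGrid, ValidationError

__all__ = [
    "PopulationTrajectory",
    "DemandLedger",
    "project_demand",
    "split_targets",
    "demand_uncertainty",
]

SSP_SCENARIOS = ("SSP1", "SSP2", "SSP3", "SSP4", "SSP5")


@dataclass(frozen=True)
class PopulationTrajectory:
    """Population (persons) on the time grid for one demographic scenario."""

    scenario: str
    values: pd.Series  # year -> persons

    def __post_init__(self) -> None:
        v = self.values.astype(float).sort_index()
        if (v <= 0).any():
            raise ValidationError(f"{self.scenario}: population must be positive")
        object.__setattr__(self, "values", v)

    def at(self, year: int) -> float:
        if year not in self.values.index:
            raise ValidationError(f"{self.scenario}: no population for year {year}")
        return float(self.values.loc[year])

    def require_projection_coverage(self, grid: TimeGrid) -> None:
        missing = [y for y in grid.projection_years if y not in self.values.index]
        if missing:
            raise ValidationError(
                f"{self.scenario}: population missing for grid years {missing}"
            )


@dataclass
class DemandLedger:
    """Per (commodity, year) food demand and the targets that meet it.

    Satisfies production_target + import_target - exports_base =
    supply_target for every cell (the supply identity).
    """

    table: pd.DataFrame  # index (commodity, year); columns food_demand,
    # supply_target, production_target, import_target

    COLUMNS = ("food_demand", "supply_target", "production_target", "import_target")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"demand ledger missing columns: {sorted(missing)}")

    @property
    def commodities(self) -> list[str]:
        return sorted(self.table.index.get_level_values("commodity").unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.table.index.get_level_values("year").unique())

    def totals(self) -> pd.DataFrame:
        """Column sums per year across commodities."""
        return self.table.groupby(level="year").sum()

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)


def project_demand(
    base: Baseline, pop: PopulationTrajectory, grid: TimeGrid | None = None
) -> pd.DataFrame:
    """Project food demand (tonnes/yr) on the grid under fixed diets.

    demand(c, t) = per_capita_supply(c) x population(t); the demand ratio
    between any two years therefore equals the population ratio for every
    commodity.
    """
    grid = grid or TimeGrid()
    pop.require_projection_coverage(grid)
    years = list(grid.projection_years)
    pops = np.array([pop.at(y) for y in years])
    demand = pd.DataFrame(
        np.outer(base.per_capita_supply.to_numpy(), pops),
        index=base.per_capita_supply.index,
        columns=years,
    )
    demand.index.name = "commodity"
    demand.columns.name = "year"
    return demand


def split_targets(demand: pd.DataFrame, base: Baseline) -> DemandLedger:
    """Split food demand into domestic-supply, production and import targets.

    The domestic-supply target solves food = S x (1 - non-food shares);
    imports take their calibrated share of S, production is the remainder
    plus baseline exports. When import_share = 1 the production target
    degenerates to exports_base. Negative targets are clipped to zero with
    a warning.
    """
    food_share = 1.0 - base.nonfood_total()
    rows = []
    for c in demand.index:
        fs = float(food_share.get(c, 1.0))
        share = float(base.import_share.get(c, 0.0))
        exports = float(base.exports_base.get(c, 0.0))
        for y in demand.columns:
            food = float(demand.loc[c, y])
            supply_target = food / fs if fs > 0 else 0.0
            import_target = share * supply_target
            production_target = supply_target - import_target + exports
            rows.append((c, int(y), food, supply_target, production_target, import_target))
    table = pd.DataFrame(
        rows,
        columns=["commodity", "year", *DemandLedger.COLUMNS],
    ).set_index(["commodity", "year"])
    neg = (table[list(DemandLedger.COLUMNS)] < 0).any(axis=1)
    if neg.any():
        warnings.warn(
            f"negative targets clipped to zero for {sorted(set(table.index[neg].get_level_values(0)))}",
            stacklevel=2,
        )
        table[list(DemandLedger.COLUMNS)] = table[list(DemandLedger.COLUMNS)].clip(lower=0.0)
    return DemandLedger(table)


def demand_uncertainty(
    base: Baseline,
    pops: list[PopulationTrajectory],
    central_scenario: str = "SSP2",
    grid: TimeGrid | None = None,
) -> pd.DataFrame:
    """Pointwise min/central/max total-demand envelope across scenarios.

    The envelope captures demand uncertainty from population growth alone;
    the central path is the designated baseline scenario.
    """
    if len(pops) < 2:
        raise ValidationError("need at least two population trajectories")
    grid = grid or TimeGrid()
    totals = {}
    for pop in pops:
        totals[pop.scenario] = project_demand(base, pop, grid).sum(axis=0)
    frame = pd.DataFrame(totals)
    if central_scenario not in frame.columns:
        raise ValidationError(f"central scenario {central_scenario!r} not supplied")
    out = pd.DataFrame(
        {
            "min": frame.min(axis=1),
            "central": frame[central_scenario],
            "max": frame.max(axis=1),
        }
    )
    out.index.name = "year"
    return out
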