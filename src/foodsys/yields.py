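"""Crop-yield shifters and feasible production on fixed cropland.

Three multiplicative shifter families act on baseline yields:

* climate -- RCP-derived multipliers (with / without CO2 fertilisation),
  equal to 1 at the first projection year;
* CCA -- climate-change adaptation (planting dates, resilient varieties,
  fertilisation), a uniform gain on the focus crops scaled by an adoption
  schedule;
* Boost -- intensified nutrient and water management, a linear yield ramp
  from the current yield to an intensification target (a fraction of the
  yield potential, or the historical maximum where that is already higher).

Shifters compose by pointwise multiplication, so combined scenarios gain
more than the sum of their parts. Feasible production keeps harvested
areas fixed at the baseline: production = area x base yield x shifter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import Baseline, CropParams, TimeGrid, ValidationError

__all__ = [
    "FOCUS_CROPS",
    "ClimateShifter",
    "ManagementScenario",
    "cca_multiplier",
    "boost_target_yield",
    "boost_path",
    "compose_shifters",
    "feasible_production",
    "default_adoption_schedule",
]

#: The six most widely grown and consumed crops; management scenarios and
#: climate shifters act on these.
FOCUS_CROPS = ("rice", "millet", "maize", "sorghum", "groundnut", "cassava")

RCPS = ("RCP2.6", "RCP6.0")


@dataclass(frozen=True)
class ClimateShifter:
    """Per-crop multiplicative climate yield modifiers over the grid.

    ``values`` is crop x year (wide); multipliers are relative to the first
    projection year (=1 there). Sorghum carries the millet series because
    no dedicated projections exist for it and the two crops have similar
    biophysical properties.
    """

    rcp: str
    co2_fertilisation: bool
    values: pd.DataFrame  # index crop, columns year

    def __post_init__(self) -> None:
        if (self.values <= 0).any().any():
            raise ValidationError("climate multipliers must be strictly positive")

    def at(self, crop: str, year: int) -> float:
        if crop in self.values.index:
            return float(self.values.loc[crop, year])
        return 1.0

    @staticmethod
    def enforce_sorghum_mapping(values: pd.DataFrame) -> pd.DataFrame:
        """Copy the millet series onto sorghum (the mapping rule)."""
        out = values.copy()
        if "millet" in out.index:
            out.loc["sorghum"] = out.loc["millet"]
        return out


def default_adoption_schedule(
    grid: TimeGrid | None = None, ramp_start: int = 2020, full_year: int = 2030
) -> dict[int, float]:
    """Linear CCA adoption ramp, 0 at ramp_start to 1 at full_year.

    Adoption is near-complete by 2030, which is why the CCA production
    effect barely grows between 2030 and 2050.
    """
    grid = grid or TimeGrid()
    span = full_year - ramp_start
    sched: dict[int, float] = {}
    for y in grid.years:
        if y <= ramp_start:
            sched[y] = 0.0
        elif y >= full_year:
            sched[y] = 1.0
        else:
            sched[y] = (y - ramp_start) / span
    return sched


@dataclass(frozen=True)
class ManagementScenario:
    """Field-management scenario: BAU, CCA, Boost or their combination."""

    label: str  # BAU | CCA | BOOST | CCA_BOOST
    cca_gain: float = 0.13
    cca_focus_crops: tuple[str, ...] = FOCUS_CROPS
    cca_gain_overrides: Mapping[str, float] = field(default_factory=dict)
    boost_fraction: float = 0.75
    adoption_schedule: Mapping[int, float] = field(
        default_factory=default_adoption_schedule
    )
    ramp_start: int = 2020

    def __post_init__(self) -> None:
        if self.label not in {"BAU", "CCA", "BOOST", "CCA_BOOST"}:
            raise ValidationError(f"unknown management label {self.label!r}")
        sched = dict(self.adoption_schedule)
        years = sorted(sched)
        fracs = [sched[y] for y in years]
        if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValidationError("adoption schedule must be non-decreasing")
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValidationError("adoption fractions must lie in [0, 1]")

    @property
    def has_cca(self) -> bool:
        return self.label in {"CCA", "CCA_BOOST"}

    @property
    def has_boost(self) -> bool:
        return self.label in {"BOOST", "CCA_BOOST"}

    def adoption(self, year: int) -> float:
        sched = dict(self.adoption_schedule)
        if year in sched:
            return sched[year]
        prior = [y for y in sched if y <= year]
        return sched[max(prior)] if prior else 0.0


def cca_multiplier(scn: ManagementScenario, crop: str, year: int) -> float:
    """Adaptation yield multiplier: 1 + gain x adoption on focus crops."""
    if not scn.has_cca or crop not in scn.cca_focus_crops:
        return 1.0
    gain = float(scn.cca_gain_overrides.get(crop, scn.cca_gain))
    return 1.0 + gain * scn.adoption(year)


def boost_target_yield(p: CropParams, scn: ManagementScenario) -> float:
    """Intensification target yield (t/ha) for 2050.

    The target is the boost fraction (default 75%) of the yield potential;
    if the historical maximum yield already exceeds that level, the
    historical maximum is the target. The target is never below the
    current base yield.
    """
    if p.yield_potential <= 0:
        raise ValidationError(f"{p.commodity}: yield_potential missing or zero")
    target = scn.boost_fraction * p.yield_potential
    if p.yield_hist_max > target:
        target = p.yield_hist_max
    return max(target, p.yield_base)


def boost_path(
    p: CropParams,
    target: float,
    grid: TimeGrid | None = None,
    ramp_start: int = 2020,
) -> pd.Series:
    """Multiplier series for a linear yield ramp to the 2050 target.

    The yield follows the straight line from yield_base at ramp_start to
    the target at the final grid year, sampled in five-year increments;
    the multiplier is path / yield_base and hits target / yield_base
    exactly at the endpoint.
    """
    grid = grid or TimeGrid()
    if ramp_start not in grid.years:
        raise ValidationError(f"ramp_start {ramp_start} is not a grid point")
    if p.yield_base <= 0:
        raise ValidationError(f"{p.commodity}: yield_base must be positive")
    if target < p.yield_base:
        warnings.warn(
            f"{p.commodity}: boost target below base yield; multiplier floored at 1",
            stacklevel=2,
        )
        target = p.yield_base
    span = grid.end_year - ramp_start
    out = {}
    for y in grid.projection_years:
        if y <= ramp_start:
            out[y] = 1.0
        else:
            frac = (y - ramp_start) / span
            out[y] = (p.yield_base + frac * (target - p.yield_base)) / p.yield_base
    s = pd.Series(out)
    s.index.name = "year"
    return s


def compose_shifters(
    climate: ClimateShifter | None,
    scn: ManagementScenario,
    params: Mapping[str, CropParams],
    grid: TimeGrid | None = None,
) -> pd.DataFrame:
    """Pointwise product of climate, CCA and Boost multipliers per crop-year.

    Multiplication is order-independent; BAU reduces to the climate
    shifter alone. Raises if the climate table covers a different crop set
    than the parameters.
    """
    grid = grid or TimeGrid()
    crops = sorted(params)
    if climate is not None:
        diff = set(climate.values.index) - set(crops)
        if diff:
            raise ValidationError(
                f"climate shifter covers crops without parameters: {sorted(diff)}"
            )
    years = list(grid.projection_years)
    composed = pd.DataFrame(1.0, index=pd.Index(crops, name="crop"), columns=years)
    composed.columns.name = "year"
    for crop in crops:
        p = params[crop]
        boost = None
        if scn.has_boost:
            target = boost_target_yield(p, scn)
            boost = boost_path(p, target, grid, ramp_start=scn.ramp_start)
        for y in years:
            m = 1.0
            if climate is not None:
                m *= climate.at(crop, y)
            m *= cca_multiplier(scn, crop, y)
            if boost is not None:
                m *= float(boost.loc[y])
            composed.loc[crop, y] = m
    if (composed <= 0).any().any():
        raise ValidationError("composed shifters must be strictly positive")
    return composed


def feasible_production(
    params: Mapping[str, CropParams],
    shifters: pd.DataFrame,
    base: Baseline | None = None,
    grid: TimeGrid | None = None,
) -> pd.DataFrame:
    """Feasible production (t/yr) on fixed cropland, commodity x year.

    Crops: area_base x yield_base x shifter. Commodities without crop
    parameters (livestock etc.) are frozen at their calibration-mean
    production, mirroring constant livestock productivity.
    """
    grid = grid or TimeGrid()
    years = list(grid.projection_years)
    rows = {}
    for crop, p in params.items():
        mult = shifters.loc[crop, years].astype(float)
        rows[crop] = p.area_base * p.yield_base * mult.to_numpy()
    if base is not None:
        for c in base.commodities:
            if c not in params:
                rows[c] = np.full(len(years), float(base.production_base.get(c, 0.0)))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=years)
    out = out.sort_index()
    out.index.name = "commodity"
    out.columns.name = "year"
    return out
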