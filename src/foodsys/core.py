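"""Core domain types and baseline calibration.

The calculator is an accounting model on a five-year time grid (2000-2050).
Historical commodity balance sheets for the calibration window (2000-2010,
yearly) are reduced to a :class:`Baseline` of per-capita supply levels,
import shares, baseline export/import volumes and non-food utilisation
shares. Everything downstream (demand projection, feasible supply, land
accounting) consumes only the Baseline plus crop parameters and scenario
inputs -- the calibration-year records are never read again.

Units are tonnes, hectares and persons throughout; per-capita and
per-calorie quantities appear only at reporting boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "BalanceSheet",
    "CropParams",
    "Baseline",
    "SUPPLY_ELEMENTS",
    "USE_ELEMENTS",
    "NONFOOD_USES",
    "load_balance_sheet",
    "load_crop_params",
    "calibrate_baseline",
]

#: Elements entering the domestic-supply identity.
SUPPLY_ELEMENTS = ("production", "imports", "exports")
#: Utilisation elements; "food" is the residual of the non-food shares.
USE_ELEMENTS = ("food", "feed", "seed", "waste", "other")
NONFOOD_USES = ("feed", "seed", "waste", "other")
#: Accepted on input but excluded from the supply identity (ledger noise
#: such as stock changes and statistical discrepancies).
PASSTHROUGH_ELEMENTS = ("stock_variation", "discrepancy")

ELEMENT_VOCABULARY = SUPPLY_ELEMENTS + USE_ELEMENTS + PASSTHROUGH_ELEMENTS


class SchemaError(ValueError):
    """Input file violates the expected schema (columns or vocabulary)."""


class ValidationError(ValueError):
    """Input data violates a model invariant (sign, coverage, identity)."""


@dataclass(frozen=True)
class TimeGrid:
    """Five-year scenario grid with a yearly historical calibration window."""

    start_year: int = 2000
    end_year: int = 2050
    step: int = 5
    calibration_start: int = 2000
    calibration_end: int = 2010
    projection_start: int = 2015

    def __post_init__(self) -> None:
        if (self.end_year - self.start_year) % self.step != 0:
            raise ValueError("step must divide end_year - start_year")
        if self.calibration_end >= self.projection_start:
            raise ValueError("calibration window must precede projection_start")
        if self.projection_start not in self.years:
            raise ValueError("projection_start must be a grid point")

    @property
    def years(self) -> tuple[int, ...]:
        """All grid points, e.g. (2000, 2005, ..., 2050)."""
        return tuple(range(self.start_year, self.end_year + 1, self.step))

    @property
    def projection_years(self) -> tuple[int, ...]:
        return tuple(y for y in self.years if y >= self.projection_start)

    @property
    def calibration_years(self) -> tuple[int, ...]:
        """Yearly calibration window (balance sheets are annual records)."""
        return tuple(range(self.calibration_start, self.calibration_end + 1))

    def calibration_grid_years(self) -> tuple[int, ...]:
        """Grid points that fall inside the calibration window."""
        return tuple(
            y for y in self.years if self.calibration_start <= y <= self.calibration_end
        )


@dataclass
class BalanceSheet:
    """Commodity x year x element ledger in tonnes/yr (long format)."""

    records: pd.DataFrame  # columns: commodity, year, element, value

    COLUMNS = ("commodity", "year", "element", "value")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise SchemaError(f"balance sheet missing columns: {sorted(missing)}")
        df = self.records.loc[:, list(self.COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
        unknown = sorted(set(df["element"]) - set(ELEMENT_VOCABULARY))
        if unknown:
            raise SchemaError(f"unknown balance-sheet elements: {unknown}")
        neg = df[df["value"] < 0]
        if not neg.empty:
            keys = neg[["commodity", "year", "element"]].to_records(index=False)
            raise ValidationError(f"negative quantities at {list(keys)[:5]}")
        dup = df.duplicated(subset=["commodity", "year", "element"])
        if dup.any():
            keys = df.loc[dup, ["commodity", "year", "element"]].to_records(index=False)
            raise ValidationError(f"duplicate ledger keys: {list(keys)[:5]}")
        self.records = df.sort_values(["commodity", "year", "element"]).reset_index(
            drop=True
        )

    @property
    def commodities(self) -> list[str]:
        return sorted(self.records["commodity"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique())

    def pivot(self) -> pd.DataFrame:
        """Wide table indexed by (commodity, year) with one column per element."""
        wide = self.records.pivot_table(
            index=["commodity", "year"],
            columns="element",
            values="value",
            aggfunc="first",
            fill_value=0.0,
        )
        for el in SUPPLY_ELEMENTS + USE_ELEMENTS:
            if el not in wide.columns:
                wide[el] = 0.0
        return wide

    def calibration_means(self, grid: TimeGrid) -> pd.DataFrame:
        """Arithmetic mean of each element over the calibration window."""
        wide = self.pivot().reset_index()
        window = wide[wide["year"].isin(grid.calibration_years)]
        return window.groupby("commodity").mean(numeric_only=True).drop(columns="year")

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BalanceSheet):
            return NotImplemented
        return self.records.equals(other.records)


def load_balance_sheet(path: str | Path, grid: TimeGrid | None = None) -> BalanceSheet:
    """Read a long-format balance-sheet CSV and validate it.

    The file must have columns ``commodity, year, element, value`` with the
    element vocabulary restricted to production / trade / utilisation terms.
    Years outside the grid (calibration window plus grid points) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    bs = BalanceSheet(df)
    if grid is not None:
        allowed = set(grid.calibration_years) | set(grid.years)
        bad = sorted(set(bs.records["year"]) - allowed)
        if bad:
            raise ValidationError(f"years outside the time grid: {bad}")
    return bs


@dataclass(frozen=True)
class CropParams:
    """Per-crop agronomic and accounting parameters.

    yield_potential is the yield attainable with non-limiting water and
    nutrients; yield_hist_max the best historically observed national yield.
    Emission factors are optional (zero disables the term).
    """

    commodity: str
    area_base: float  # ha
    yield_base: float  # t/ha
    yield_potential: float  # t/ha
    yield_hist_max: float  # t/ha
    kcal_per_tonne: float  # kcal/t
    ef_area: float = 0.0  # t CO2e/ha/yr
    ef_product: float = 0.0  # t CO2e/t

    def __post_init__(self) -> None:
        for name in (
            "area_base",
            "yield_base",
            "yield_potential",
            "yield_hist_max",
            "kcal_per_tonne",
            "ef_area",
            "ef_product",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.commodity}: {name} must be >= 0")


def load_crop_params(path: str | Path) -> dict[str, CropParams]:
    """Read a crop-parameter CSV (one row per crop) into CropParams."""
    df = pd.read_csv(path)
    required = {
        "commodity",
        "area_base",
        "yield_base",
        "yield_potential",
        "yield_hist_max",
        "kcal_per_tonne",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"crop parameter file missing columns: {sorted(missing)}")
    out: dict[str, CropParams] = {}
    for _, row in df.iterrows():
        out[row["commodity"]] = CropParams(
            commodity=row["commodity"],
            area_base=float(row["area_base"]),
            yield_base=float(row["yield_base"]),
            yield_potential=float(row["yield_potential"]),
            yield_hist_max=float(row["yield_hist_max"]),
            kcal_per_tonne=float(row["kcal_per_tonne"]),
            ef_area=float(row.get("ef_area", 0.0)) if "ef_area" in df.columns else 0.0,
            ef_product=float(row.get("ef_product", 0.0))
            if "ef_product" in df.columns
            else 0.0,
        )
    return out


@dataclass
class Baseline:
    """Calibration-window means driving all projections.

    per_capita_supply is in tonnes/person/yr (kg/capita only at reporting).
    nonfood_factors holds the feed/seed/waste/other shares of domestic
    supply; the food share is the remainder.
    """

    per_capita_supply: pd.Series  # commodity -> t/person/yr
    import_share: pd.Series  # commodity -> [0, 1]
    exports_base: pd.Series  # commodity -> t/yr
    imports_base: pd.Series  # commodity -> t/yr
    production_base: pd.Series  # commodity -> t/yr
    nonfood_factors: pd.DataFrame  # commodity x (feed, seed, waste, other)
    population_base: float  # persons (calibration mean)
    zero_supply_commodities: tuple[str, ...] = ()

    @property
    def commodities(self) -> list[str]:
        return list(self.per_capita_supply.index)

    def nonfood_total(self) -> pd.Series:
        """Total non-food share of domestic supply per commodity."""
        return self.nonfood_factors.sum(axis=1).clip(upper=1.0)

    def kcal_per_capita_day(self, kcal_per_tonne: Mapping[str, float]) -> float:
        """Baseline daily per-capita calorie availability (kcal/cap/day)."""
        total = 0.0
        for c in self.commodities:
            total += self.per_capita_supply[c] * float(kcal_per_tonne.get(c, 0.0))
        return total / 365.0


def calibrate_baseline(
    bs: BalanceSheet,
    population: Mapping[int, float] | "pd.Series",
    grid: TimeGrid | None = None,
) -> Baseline:
    """Reduce calibration-window balance sheets to baseline parameters.

    All element means are arithmetic means over the yearly calibration
    window; the population mean is taken over the grid points inside the
    window. Commodities whose mean domestic supply is zero are flagged and
    carried with import_share 0 rather than dropped.
    """
    grid = grid or TimeGrid()
    pop = pd.Series(dict(population)).astype(float)
    cal_pop_years = [y for y in grid.calibration_grid_years() if y in pop.index]
    if not cal_pop_years:
        raise ValidationError(
            "population trajectory has no values inside the calibration window"
        )
    pop_base = float(pop.loc[cal_pop_years].mean())
    if pop_base <= 0:
        raise ValidationError("calibration population must be positive")

    wide = bs.pivot().reset_index()
    missing_years: dict[str, list[int]] = {}
    for c, sub in wide.groupby("commodity"):
        absent = sorted(set(grid.calibration_years) - set(sub["year"]))
        if absent:
            missing_years[str(c)] = absent
    if missing_years:
        raise ValidationError(
            f"balance sheet does not cover the calibration window: {missing_years}"
        )

    means = bs.calibration_means(grid)
    supply = means["production"] + means["imports"] - means["exports"]
    neg = supply[supply < -1e-9]
    if not neg.empty:
        raise ValidationError(
            f"negative mean domestic supply for {sorted(neg.index)}"
        )
    supply = supply.clip(lower=0.0)
    zero = supply[supply <= 0.0].index

    with np.errstate(divide="ignore", invalid="ignore"):
        import_share = (means["imports"] / supply).where(supply > 0, 0.0)
        nonfood = pd.DataFrame(
            {u: (means[u] / supply).where(supply > 0, 0.0) for u in NONFOOD_USES}
        )
    import_share = import_share.clip(lower=0.0, upper=1.0)
    nonfood = nonfood.clip(lower=0.0)
    over = nonfood.sum(axis=1)
    if (over > 1.0 + 1e-9).any():
        bad = sorted(over[over > 1.0 + 1e-9].index)
        warnings.warn(f"non-food shares exceed 1 for {bad}; rescaling", stacklevel=2)
        nonfood.loc[over > 1.0] = nonfood.loc[over > 1.0].div(over[over > 1.0], axis=0)

    return Baseline(
        per_capita_supply=means["food"] / pop_base,
        import_share=import_share,
        exports_base=means["exports"],
        imports_base=means["imports"],
        production_base=means["production"],
        nonfood_factors=nonfood,
        population_base=pop_base,
        zero_supply_commodities=tuple(sorted(zero)),
    )
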