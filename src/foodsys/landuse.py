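"""Cropland-expansion requirements, the land-availability cap, and crop GHG.

The land question asked here is a counterfactual: how much cultivated
area would be needed to meet the domestic-supply targets *without*
increasing imports (imports frozen at baseline absolute volumes)? A
feedback cap truncates the requirement at the available national land
area, reporting the unmet residual. Crop GHG emissions are a linear
accounting over areas and production volumes with user-supplied factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import Baseline, CropParams, TimeGrid, ValidationError
from .demand import DemandLedger

__all__ = [
    "LandReport",
    "GhgReport",
    "required_area",
    "apply_land_cap",
    "crop_ghg",
    "expansion_percent",
]


@dataclass
class LandReport:
    """Required cultivated area per year against the baseline area."""

    per_crop: pd.DataFrame  # crop x year, ha
    totals: pd.DataFrame  # year: required_area, expansion_ha, expansion_pct,
    # capped, land_cap, residual_area
    area_base_total: float  # ha


@dataclass
class GhgReport:
    """Crop-production emissions per year, split by accounting term."""

    totals: pd.DataFrame  # year: area_term_mt, product_term_mt, total_mt


def expansion_percent(required_area: float, area_base: float) -> float:
    """Relative cropland expansion in percent: (required - base) / base."""
    if area_base <= 0:
        raise ValidationError("baseline area must be positive")
    return 100.0 * (required_area - area_base) / area_base


def required_area(
    ledger: DemandLedger,
    yields_t: pd.DataFrame,
    base: Baseline,
    params: Mapping[str, CropParams],
    grid: TimeGrid | None = None,
) -> LandReport:
    """Cultivated area needed to meet supply targets at frozen imports.

    Per crop and year: area = max(0, supply target - baseline imports +
    baseline exports) / yield, with yields (t/ha) from the active
    scenario (base yield x shifter). Only commodities with crop
    parameters occupy land; totals are compared against the summed
    baseline harvested area.
    """
    grid = grid or TimeGrid()
    years = list(grid.projection_years)
    crops = sorted(params)
    area = pd.DataFrame(0.0, index=pd.Index(crops, name="crop"), columns=years)
    for c in crops:
        imports_fixed = float(base.imports_base.get(c, 0.0))
        exports = float(base.exports_base.get(c, 0.0))
        for y in years:
            target = float(ledger.table.loc[(c, y), "supply_target"])
            need = max(0.0, target - imports_fixed + exports)
            yld = float(yields_t.loc[c, y])
            if yld <= 0:
                if need > 0:
                    raise ValidationError(f"{c}: zero yield with positive requirement")
                continue
            area.loc[c, y] = need / yld
    area_base_total = float(sum(params[c].area_base for c in crops))
    required = area.sum(axis=0)
    totals = pd.DataFrame(
        {
            "required_area": required,
            "expansion_ha": required - area_base_total,
            "expansion_pct": [
                expansion_percent(v, area_base_total) for v in required
            ],
            "capped": False,
            "land_cap": np.nan,
            "residual_area": 0.0,
        }
    )
    totals.index.name = "year"
    return LandReport(per_crop=area, totals=totals, area_base_total=area_base_total)


def apply_land_cap(report: LandReport, cap: float) -> LandReport:
    """Truncate the area requirement at the available land area.

    Capped years keep the unmet requirement as ``residual_area`` so the
    shortfall is visible downstream.
    """
    if cap <= 0:
        raise ValidationError("land cap must be positive")
    totals = report.totals.copy()
    over = totals["required_area"] > cap
    totals["land_cap"] = cap
    totals["capped"] = over
    totals["residual_area"] = (totals["required_area"] - cap).clip(lower=0.0)
    totals.loc[over, "required_area"] = cap
    totals["expansion_ha"] = totals["required_area"] - report.area_base_total
    totals["expansion_pct"] = [
        expansion_percent(v, report.area_base_total) for v in totals["required_area"]
    ]
    per_crop = report.per_crop.copy()
    # scale crop areas proportionally in capped years so the split stays consistent
    for y in per_crop.columns:
        tot = per_crop[y].sum()
        if bool(over.loc[y]) and tot > 0:
            per_crop[y] *= cap / tot
    return LandReport(per_crop=per_crop, totals=totals, area_base_total=report.area_base_total)


def crop_ghg(
    production: pd.DataFrame,
    areas: pd.DataFrame,
    params: Mapping[str, CropParams],
) -> GhgReport:
    """Crop GHG emissions in Mt CO2e per year.

    emissions(t) = sum_c area(c,t) x ef_area(c) + production(c,t) x
    ef_product(c). Commodities without factors contribute zero.
    """
    years = list(areas.columns)
    area_term = pd.Series(0.0, index=years)
    product_term = pd.Series(0.0, index=years)
    for c, p in params.items():
        if c in areas.index:
            area_term += areas.loc[c, years].astype(float) * p.ef_area
        if c in production.index:
            product_term += production.loc[c, years].astype(float) * p.ef_product
    totals = pd.DataFrame(
        {
            "area_term_mt": area_term / 1e6,
            "product_term_mt": product_term / 1e6,
            "total_mt": (area_term + product_term) / 1e6,
        }
    )
    totals.index.name = "year"
    return GhgReport(totals=totals)
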