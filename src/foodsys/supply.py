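"""Feasible supply, supply gaps and per-capita calorie availability.

Feasible domestic supply follows the same identity as the demand-side
targets but driven by what can actually be produced: imports keep their
calibration share of the *feasible* domestic supply (they do not expand
to fill shortfalls, which is exactly why a production gap becomes a
calorie deficit), exports stay at baseline volumes, and the calibrated
non-food shares are removed before food reaches consumers. A gap-filling
import mode exists for counterfactuals but is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Baseline, CropParams, TimeGrid, ValidationError
from .demand import DemandLedger, PopulationTrajectory

__all__ = [
    "GapReport",
    "CalorieReport",
    "feasible_supply",
    "gap_report",
    "scenario_delta",
    "calorie_availability",
]

_SHARE_CAP = 1.0 - 1e-9  # import shares at/above this freeze imports at baseline


@dataclass
class GapReport:
    """Supply gap per (commodity, year) and aggregated per year.

    gap = max(0, production target - feasible production); shares are
    expressed relative to the production target.
    """

    cells: pd.DataFrame  # index (commodity, year): production_target,
    # feasible_production, gap, gap_share
    totals: pd.DataFrame  # index year: same columns, summed / recomputed

    def gap_share_at(self, year: int) -> float:
        return float(self.totals.loc[year, "gap_share"])

    def rounded(self, percent_digits: int = 0, tonnes_to: int = 1000) -> pd.DataFrame:
        """Reporting view: shares in % and tonnes rounded (default nearest
        percent / nearest thousand tonnes)."""
        out = self.totals.copy()
        for col in ("production_target", "feasible_production", "gap"):
            out[col] = (out[col] / tonnes_to).round() * tonnes_to
        out["gap_share"] = (out["gap_share"] * 100).round(percent_digits)
        return out


@dataclass
class CalorieReport:
    """Daily per-capita calorie availability per year plus baseline level."""

    kcal_per_capita_day: pd.Series  # year -> kcal/cap/day
    baseline_level: float  # kcal/cap/day from calibration diet

    def deficit(self) -> pd.Series:
        """Shortfall vs the fixed-diet baseline level (>= 0)."""
        return (self.baseline_level - self.kcal_per_capita_day).clip(lower=0.0)


def feasible_supply(
    production: pd.DataFrame,
    base: Baseline,
    import_mode: str = "share",
    ledger: DemandLedger | None = None,
) -> pd.DataFrame:
    """Food available for consumption (t/yr) per commodity x year.

    Domestic supply S solves S = production + imports - exports with
    imports = share x S, i.e. S = (production - exports) / (1 - share);
    food supply is S x (1 - non-food shares). For fully import-dependent
    commodities (share ~ 1) the share rule is vacuous -- domestic supply
    *is* imports -- so their supply follows the demand-side target when
    the ledger is given, else baseline import volumes. In
    ``import_mode="gap_fill"`` imports instead expand so food supply meets
    the demand ledger exactly for every commodity.
    """
    if import_mode not in {"share", "gap_fill"}:
        raise ValidationError(f"unknown import mode {import_mode!r}")
    if import_mode == "gap_fill":
        if ledger is None:
            raise ValidationError("gap_fill mode requires the demand ledger")
        food = ledger.table["food_demand"].unstack("year")
        return food.reindex(index=production.index, columns=production.columns)

    food_share = 1.0 - base.nonfood_total()
    out = pd.DataFrame(0.0, index=production.index, columns=production.columns)
    clipped = []
    for c in production.index:
        share = float(base.import_share.get(c, 0.0))
        exports = float(base.exports_base.get(c, 0.0))
        fs = float(food_share.get(c, 1.0))
        for y in production.columns:
            prod = float(production.loc[c, y])
            if share >= _SHARE_CAP:
                if ledger is not None and (c, int(y)) in ledger.table.index:
                    supply = float(ledger.table.loc[(c, int(y)), "supply_target"])
                else:
                    supply = float(base.imports_base.get(c, 0.0)) + prod - exports
            else:
                supply = (prod - exports) / (1.0 - share)
            if supply < 0:
                clipped.append((c, int(y)))
                supply = 0.0
            out.loc[c, y] = supply * fs
    if clipped:
        warnings.warn(
            f"exports exceed production+imports; supply clipped to 0 at {clipped[:5]}",
            stacklevel=2,
        )
    return out


def gap_report(ledger: DemandLedger, production: pd.DataFrame) -> GapReport:
    """Quantify the shortfall of feasible production against targets."""
    target = ledger.table["production_target"].unstack("year")
    missing = set(target.index) - set(production.index)
    if missing:
        raise ValidationError(f"feasible production missing commodities: {sorted(missing)}")
    production = production.reindex(index=target.index, columns=target.columns)
    gap = (target - production).clip(lower=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = (gap / target).where(target > 0, 0.0)
    cells = pd.concat(
        {
            "production_target": target.stack(),
            "feasible_production": production.stack(),
            "gap": gap.stack(),
            "gap_share": share.stack(),
        },
        axis=1,
    )
    cells.index.names = ["commodity", "year"]
    totals = cells.groupby(level="year")[
        ["production_target", "feasible_production", "gap"]
    ].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        totals["gap_share"] = (totals["gap"] / totals["production_target"]).where(
            totals["production_target"] > 0, 0.0
        )
    return GapReport(cells=cells, totals=totals)


def scenario_delta(gap_bau: GapReport, gap_scn: GapReport) -> pd.DataFrame:
    """Additional feasible production of a scenario over BAU, per year.

    Returns delta tonnes and delta as a share of the (common) production
    target. Raises if the two reports were built against different targets.
    """
    t_bau = gap_bau.totals["production_target"]
    t_scn = gap_scn.totals["production_target"]
    if not np.allclose(t_bau.to_numpy(), t_scn.to_numpy(), rtol=1e-9):
        raise ValidationError("gap reports have different production targets")
    delta = gap_scn.totals["feasible_production"] - gap_bau.totals["feasible_production"]
    out = pd.DataFrame({"delta_tonnes": delta, "delta_share": delta / t_bau})
    out.index.name = "year"
    return out


def calorie_availability(
    supply_food: pd.DataFrame,
    pop: PopulationTrajectory,
    params: "dict[str, CropParams] | pd.Series | dict[str, float]",
    base: Baseline | None = None,
) -> CalorieReport:
    """Daily per-capita calorie availability from the food supply.

    kcal/cap/day(t) = sum_c supply_food(c, t) x kcal_per_tonne(c) /
    population(t) / 365. Energy factors must exist for every commodity
    with non-zero supply.
    """
    if isinstance(params, dict) and params and isinstance(
        next(iter(params.values())), CropParams
    ):
        kcal = {c: p.kcal_per_tonne for c, p in params.items()}
    else:
        kcal = {c: float(v) for c, v in dict(params).items()}

    missing = [
        c
        for c in supply_food.index
        if c not in kcal and (supply_food.loc[c] > 0).any()
    ]
    if missing:
        raise ValidationError(
            f"missing energy content for commodities with supply: {sorted(missing)}"
        )
    factors = pd.Series({c: kcal.get(c, 0.0) for c in supply_food.index})
    yearly = supply_food.mul(factors, axis=0).sum(axis=0)
    pops = pd.Series({y: pop.at(int(y)) for y in supply_food.columns})
    per_cap = yearly / pops / 365.0
    per_cap.index.name = "year"
    baseline_level = base.kcal_per_capita_day(kcal) if base is not None else float("nan")
    return CalorieReport(kcal_per_capita_day=per_cap, baseline_level=baseline_level)
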