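"""Pathway configuration, scenario-grid execution and report export.

A *pathway* is one coherent scenario combination -- population scenario x
climate scenario x CO2 switch x field management -- plus the fixed-factor
assumptions. ``run_pathway`` executes the calculation chain
calibrate -> demand -> yields -> supply -> land use in order and returns
every report; ``run_grid`` sweeps a list of pathways and builds
uncertainty envelopes (population scenarios for demand, the CO2 on/off
band for production). Runs are deterministic given config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .core import Baseline, TimeGrid, ValidationError, calibrate_baseline
from .demand import (
    DemandLedger,
    PopulationTrajectory,
    SSP_SCENARIOS,
    demand_uncertainty,
    project_demand,
    split_targets,
)
from .landuse import GhgReport, LandReport, apply_land_cap, crop_ghg, required_area
from .supply import (
    CalorieReport,
    GapReport,
    calorie_availability,
    feasible_supply,
    gap_report,
)
from .synth import FixtureBundle, gambia_fixture
from .yields import (
    ClimateShifter,
    ManagementScenario,
    RCPS,
    compose_shifters,
    feasible_production,
)

__all__ = ["PathwayConfig", "PathwayResult", "run_pathway", "run_grid", "export_report"]

log = logging.getLogger("foodsys")

MANAGEMENT_LABELS = ("BAU", "CCA", "BOOST", "CCA_BOOST")


@dataclass(frozen=True)
class PathwayConfig:
    """One scenario combination plus fixed-factor assumptions."""

    ssp: str = "SSP2"
    rcp: str = "RCP2.6"
    co2_fertilisation: bool | None = None  # None -> central (mean of on/off)
    management: str = "BAU"
    reference_year: int = 2020  # for growth reporting
    land_cap: float | None = None  # None -> fixture default
    import_mode: str = "share"
    seed: int = 0
    cca_gain: float = 0.13
    boost_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.ssp not in SSP_SCENARIOS:
            raise ValidationError(f"unknown population scenario {self.ssp!r}")
        if self.rcp not in RCPS:
            raise ValidationError(f"unknown climate scenario {self.rcp!r}")
        if self.management not in MANAGEMENT_LABELS:
            raise ValidationError(f"unknown management label {self.management!r}")

    def scenario(self) -> ManagementScenario:
        return ManagementScenario(
            label=self.management,
            cca_gain=self.cca_gain,
            boost_fraction=self.boost_fraction,
        )

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PathwayConfig":
        """Load a ``pathway:`` block from a YAML file; kwargs override."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        block = doc.get("pathway", doc)
        known = set(cls.__dataclass_fields__)
        unknown = set(block) - known
        if unknown:
            raise ValidationError(f"unknown pathway keys: {sorted(unknown)}")
        block.update(overrides)
        return cls(**block)


@dataclass
class PathwayResult:
    """All reports of one pathway run, sharing a commodity/year index."""

    config: PathwayConfig
    baseline: Baseline
    ledger: DemandLedger
    feasible: pd.DataFrame  # commodity x year tonnes
    supply_food: pd.DataFrame  # commodity x year tonnes for consumption
    gaps: GapReport
    calories: CalorieReport
    land: LandReport
    ghg: GhgReport
    metadata: dict = field(default_factory=dict)


def _climate_values(
    bundle: FixtureBundle, cfg: PathwayConfig
) -> ClimateShifter | None:
    on = bundle.climate[(cfg.rcp, True)]
    off = bundle.climate[(cfg.rcp, False)]
    if cfg.co2_fertilisation is None:
        central = (on.values + off.values) / 2.0
        return ClimateShifter(rcp=cfg.rcp, co2_fertilisation=True, values=central)
    return on if cfg.co2_fertilisation else off


def run_pathway(
    cfg: PathwayConfig, bundle: FixtureBundle | None = None
) -> PathwayResult:
    """Execute one pathway end to end on an input bundle.

    Stages run in dataflow order; any stage error is re-raised with the
    stage name attached. With no bundle the packaged deterministic
    fixture is used.
    """
    bundle = bundle or gambia_fixture()
    grid = bundle.grid
    stage = "calibrate"
    try:
        pop = bundle.populations[cfg.ssp]
        base = calibrate_baseline(bundle.balance_sheet, pop.values.to_dict(), grid)
        log.info("calibrated %d commodities", len(base.commodities))

        stage = "demand"
        demand = project_demand(base, pop, grid)
        ledger = split_targets(demand, base)
        log.info("demand ledger: %d cells", len(ledger.table))

        stage = "yields"
        climate = _climate_values(bundle, cfg)
        shifters = compose_shifters(climate, cfg.scenario(), bundle.crop_params, grid)
        feasible = feasible_production(bundle.crop_params, shifters, base, grid)

        stage = "supply"
        supply_food = feasible_supply(
            feasible, base, import_mode=cfg.import_mode, ledger=ledger
        )
        gaps = gap_report(ledger, feasible)
        calories = calorie_availability(supply_food, pop, bundle.kcal_per_tonne, base)

        stage = "landuse"
        years = list(grid.projection_years)
        yields_t = pd.DataFrame(
            {
                y: {
                    c: bundle.crop_params[c].yield_base * float(shifters.loc[c, y])
                    for c in bundle.crop_params
                }
                for y in years
            }
        )
        land = required_area(ledger, yields_t, base, bundle.crop_params, grid)
        cap = cfg.land_cap if cfg.land_cap is not None else bundle.land_cap
        land = apply_land_cap(land, cap)
        ghg = crop_ghg(feasible, land.per_crop, bundle.crop_params)
    except Exception as err:
        try:
            wrapped = type(err)(f"[stage: {stage}] {err}")
        except Exception:  # exception types with non-str constructors
            wrapped = RuntimeError(f"[stage: {stage}] {err}")
        raise wrapped from err

    return PathwayResult(
        config=cfg,
        baseline=base,
        ledger=ledger,
        feasible=feasible,
        supply_food=supply_food,
        gaps=gaps,
        calories=calories,
        land=land,
        ghg=ghg,
        metadata={"config_hash": cfg.hash(), "seed": cfg.seed},
    )


def run_grid(
    cfgs: list[PathwayConfig], bundle: FixtureBundle | None = None
) -> tuple[dict[str, PathwayResult], dict[str, pd.DataFrame]]:
    """Run several pathways and build cross-scenario envelopes.

    Returns results keyed by config hash plus pointwise min/central/max
    envelopes for total demand (across population scenarios) and total
    feasible production (across CO2 switches / scenarios).
    """
    if not cfgs:
        raise ValidationError("need at least one pathway config")
    bundle = bundle or gambia_fixture()
    results = {cfg.hash(): run_pathway(cfg, bundle) for cfg in cfgs}

    commodity_sets = {tuple(r.feasible.index) for r in results.values()}
    if len(commodity_sets) > 1:
        raise ValidationError("inconsistent commodity sets across pathway results")

    some = next(iter(results.values()))
    base = some.baseline
    pops = [bundle.populations[s] for s in SSP_SCENARIOS]
    demand_env = demand_uncertainty(base, pops, central_scenario="SSP2", grid=bundle.grid)

    prod = pd.DataFrame(
        {h: r.feasible.sum(axis=0) for h, r in results.items()}
    )
    central_hash = cfgs[0].hash()
    prod_env = pd.DataFrame(
        {
            "min": prod.min(axis=1),
            "central": prod[central_hash],
            "max": prod.max(axis=1),
        }
    )
    prod_env.index.name = "year"
    return results, {"demand": demand_env, "production": prod_env}


def export_report(
    result: PathwayResult, directory: str | Path, percent_digits: int = 0
) -> dict[str, Path]:
    """Write tidy CSVs for every report plus a run manifest.

    Exports are byte-identical across runs for identical (config, seed)
    and round-trip readable with pandas.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = directory / f"{name}.csv"
        df.reset_index().to_csv(path, index=False, float_format="%.6f")
        files[name] = path

    write("demand_ledger", result.ledger.table)
    write("feasible_production", result.feasible.stack().rename("tonnes").to_frame())
    write("supply_food", result.supply_food.stack().rename("tonnes").to_frame())
    write("gap_cells", result.gaps.cells)
    write("gap_totals", result.gaps.rounded(percent_digits=percent_digits))
    write(
        "calories",
        result.calories.kcal_per_capita_day.rename("kcal_per_capita_day").to_frame(),
    )
    write("land", result.land.totals)
    write("ghg", result.ghg.totals)

    manifest = {
        "config": {k: v for k, v in result.config.__dict__.items()},
        "config_hash": result.metadata["config_hash"],
        "seed": result.metadata["seed"],
        "commodities": list(result.feasible.index),
        "years": [int(y) for y in result.feasible.columns],
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    files["manifest"] = manifest_path
    return files
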