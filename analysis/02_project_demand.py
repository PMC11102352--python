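#!/usr/bin/env python
"""Project food demand to 2050 and split it into production/import targets.

Diets are fixed at the calibration window, so demand scales with each
population scenario; the envelope across the five scenarios is the demand
uncertainty band. Targets keep import shares and export volumes constant.
"""

from pathlib import Path

from foodsys.core import calibrate_baseline
from foodsys.demand import demand_uncertainty, project_demand, split_targets
from foodsys.synth import gambia_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "demand"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = gambia_fixture()
    pop = bundle.populations["SSP2"]
    base = calibrate_baseline(bundle.balance_sheet, pop.values.to_dict(), bundle.grid)

    demand = project_demand(base, pop, bundle.grid)
    ledger = split_targets(demand, base)
    ledger.to_csv(OUT / "demand_ledger.csv")

    env = demand_uncertainty(base, list(bundle.populations.values()),
                             grid=bundle.grid)
    env.to_csv(OUT / "demand_envelope.csv", float_format="%.1f")

    totals = ledger.totals()
    growth = 100 * (totals.loc[2050, "food_demand"] / totals.loc[2020, "food_demand"] - 1)
    lo = 100 * (env.loc[2050, "min"] / env.loc[2020, "central"] - 1)
    hi = 100 * (env.loc[2050, "max"] / env.loc[2020, "central"] - 1)
    print(f"baseline food demand 2020->2050: +{growth:.0f}% "
          f"(scenario envelope {lo:+.0f}% .. {hi:+.0f}%)")
    print(f"2050 production target: {totals.loc[2050, 'production_target']:,.0f} t; "
          f"import target: {totals.loc[2050, 'import_target']:,.0f} t")
    print(f"wrote ledgers to {OUT}")


if __name__ == "__main__":
    main()
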