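#!/usr/bin/env python
"""Cropland needed to meet demand without extra imports, and crop GHG.

The land counterfactual freezes imports at baseline volumes and asks how
much cultivated area each scenario's yields would require; the national
land-area cap truncates infeasible expansions. Emissions combine per-area
and per-tonne factors over the resulting areas and production volumes.
"""

from pathlib import Path

import pandas as pd

from foodsys.pipeline import PathwayConfig, run_pathway
from foodsys.synth import gambia_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "land"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = gambia_fixture()
    rows = []
    for mgmt in ("BAU", "CCA", "BOOST", "CCA_BOOST"):
        r = run_pathway(PathwayConfig(management=mgmt), bundle)
        land = r.land.totals.loc[2050]
        ghg = r.ghg.totals.loc[2050]
        rows.append({
            "management": mgmt,
            "required_area_ha": float(land["required_area"]),
            "expansion_pct": float(land["expansion_pct"]),
            "capped": bool(land["capped"]),
            "residual_area_ha": float(land["residual_area"]),
            "ghg_mt_co2e": float(ghg["total_mt"]),
        })
        r.land.totals.to_csv(OUT / f"land_{mgmt.lower()}.csv",
                             float_format="%.1f")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "land_summary_2050.csv", index=False, float_format="%.3f")

    print(f"baseline harvested area: {r.land.area_base_total:,.0f} ha; "
          f"land cap {bundle.land_cap:,.0f} ha")
    for row in rows:
        capped = " (capped at land area)" if row["capped"] else ""
        print(f"  {row['management']:10s}: requires "
              f"{row['required_area_ha'] + row['residual_area_ha']:,.0f} ha "
              f"({row['expansion_pct'] + 100 * row['residual_area_ha'] / 350000:.0f}% "
              f"expansion){capped}; crop GHG {row['ghg_mt_co2e']:.2f} Mt CO2e")
    print(f"wrote land/GHG tables to {OUT}")


if __name__ == "__main__":
    main()
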