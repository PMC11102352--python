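#!/usr/bin/env python
"""Write the packaged deterministic fixture and a noisy synthetic input set.

The fixture is the Gambia-like bundle every later step consumes: six focus
crops on 350,000 ha, four further commodities, constant 2000-2010 balance
sheets, five population scenarios and four climate shifter series. The
seeded synthetic set demonstrates the generator with lognormal yearly noise.
"""

from pathlib import Path

import pandas as pd

from foodsys.synth import GeneratorSpec, gambia_fixture, generate_balance_sheets, \
    generate_crop_params

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = gambia_fixture()
    bundle.balance_sheet.to_csv(OUT / "fixture_balance_sheet.csv")
    pd.DataFrame(
        [
            {
                "commodity": p.commodity,
                "area_base": p.area_base,
                "yield_base": p.yield_base,
                "yield_potential": p.yield_potential,
                "yield_hist_max": p.yield_hist_max,
                "kcal_per_tonne": p.kcal_per_tonne,
                "ef_area": p.ef_area,
                "ef_product": p.ef_product,
            }
            for p in bundle.crop_params.values()
        ]
    ).to_csv(OUT / "fixture_crop_params.csv", index=False)
    pd.DataFrame(
        [
            {"scenario": s, "year": int(y), "persons": float(v)}
            for s, t in bundle.populations.items()
            for y, v in t.values.items()
        ]
    ).to_csv(OUT / "fixture_population.csv", index=False)

    spec = GeneratorSpec(seed=20260923, noise_cv=0.05)
    bs = generate_balance_sheets(spec, generate_crop_params(spec))
    bs.to_csv(OUT / "synthetic_balance_sheet.csv")

    area = sum(p.area_base for p in bundle.crop_params.values())
    print(f"fixture: {len(bundle.balance_sheet.commodities)} commodities, "
          f"{area:,.0f} ha harvested area")
    print(f"synthetic: {len(bs.records)} noisy ledger records (seed {spec.seed})")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
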