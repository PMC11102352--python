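"""Feasible supply, gap accounting and calorie availability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from foodsys.core import TimeGrid, ValidationError
from foodsys.demand import DemandLedger, PopulationTrajectory, project_demand, \
    split_targets
from foodsys.supply import (
    calorie_availability,
    feasible_supply,
    gap_report,
    scenario_delta,
)

from test_demand import make_baseline, make_pop


def ledger_from(target_frame, base):
    """DemandLedger with targets chosen directly (supply identity respected)."""
    rows = []
    for c in target_frame.index:
        share = float(base.import_share[c])
        exports = float(base.exports_base[c])
        fs = 1.0 - float(base.nonfood_factors.loc[c].sum())
        for y in target_frame.columns:
            prod_target = float(target_frame.loc[c, y])
            supply = (prod_target - exports) / (1 - share) if share < 1 else prod_target
            rows.append((c, int(y), supply * fs, supply, prod_target, share * supply))
    table = pd.DataFrame(
        rows, columns=["commodity", "year", *DemandLedger.COLUMNS]
    ).set_index(["commodity", "year"])
    return DemandLedger(table)


class TestFeasibleSupply:
    def test_import_share_multiplies_domestic_production(self, grid):
        """17 kt production with an 83% import share supplies 100 kt."""
        base = make_baseline(grid, import_share=0.83, commodities=("rice",))
        prod = pd.DataFrame({2020: [17_000.0]},
                            index=pd.Index(["rice"], name="commodity"))
        food = feasible_supply(prod, base)
        assert food.loc["rice", 2020] == pytest.approx(100_000.0)

    def test_closure_feasible_equals_target_recovers_demand(self, grid):
        """Forcing feasible production onto the targets returns exactly the
        food demand at every cell."""
        base = make_baseline(grid, import_share=0.3, exports=5.0, nonfood=0.2)
        pop = make_pop(grid)
        ledger = split_targets(project_demand(base, pop, grid), base)
        target = ledger.table["production_target"].unstack("year")
        food = feasible_supply(target, base, ledger=ledger)
        expected = ledger.table["food_demand"].unstack("year")
        pd.testing.assert_frame_equal(food, expected, rtol=1e-9)

    def test_negative_supply_clipped_with_warning(self, grid):
        base = make_baseline(grid, import_share=0.0, exports=50.0)
        prod = pd.DataFrame({2020: [10.0, 100.0]},
                            index=pd.Index(["a", "b"], name="commodity"))
        with pytest.warns(UserWarning, match="clipped"):
            food = feasible_supply(prod, base)
        assert food.loc["a", 2020] == 0.0
        assert food.loc["b", 2020] == pytest.approx(50.0)

    @given(
        share=st.floats(0.0, 0.9),
        nonfood=st.floats(0.0, 0.6),
        prod=st.floats(10.0, 1e5),
        exports_frac=st.floats(0.0, 0.9),
    )
    def test_supply_identity_per_cell(self, share, nonfood, prod, exports_frac):
        """food = (production + imports - exports) x food share, with
        imports = share x domestic supply."""
        grid = TimeGrid()
        exports = exports_frac * prod
        base = make_baseline(grid, import_share=share, exports=exports,
                             nonfood=nonfood, commodities=("c",))
        frame = pd.DataFrame({2020: [prod]}, index=pd.Index(["c"], name="commodity"))
        food = feasible_supply(frame, base)
        supply = (prod - exports) / (1 - share)
        imports = share * supply
        assert food.loc["c", 2020] == pytest.approx(
            (prod + imports - exports) * (1 - nonfood), rel=1e-9
        )

    def test_gap_fill_mode_meets_demand(self, grid):
        base = make_baseline(grid, import_share=0.3)
        pop = make_pop(grid)
        ledger = split_targets(project_demand(base, pop, grid), base)
        prod = ledger.table["production_target"].unstack("year") * 0.5  # shortfall
        food = feasible_supply(prod, base, import_mode="gap_fill", ledger=ledger)
        pd.testing.assert_frame_equal(
            food, ledger.table["food_demand"].unstack("year")
        )


class TestGapReport:
    def test_gap_and_share_arithmetic(self, grid):
        base = make_baseline(grid, commodities=("c",))
        ledger = ledger_from(
            pd.DataFrame({2050: [100.0]}, index=pd.Index(["c"], name="commodity")),
            base,
        )
        prod = pd.DataFrame({2050: [53.0]}, index=pd.Index(["c"], name="commodity"))
        rep = gap_report(ledger, prod)
        cell = rep.cells.loc[("c", 2050)]
        assert cell["gap"] == pytest.approx(47.0)
        assert cell["gap_share"] == pytest.approx(0.47)

    def test_surplus_production_gives_zero_gap(self, grid):
        base = make_baseline(grid, commodities=("c",))
        ledger = ledger_from(
            pd.DataFrame({2050: [100.0]}, index=pd.Index(["c"], name="commodity")),
            base,
        )
        prod = pd.DataFrame({2050: [120.0]}, index=pd.Index(["c"], name="commodity"))
        rep = gap_report(ledger, prod)
        assert rep.cells.loc[("c", 2050), "gap"] == 0.0

    def test_zero_target_zero_share(self, grid):
        base = make_baseline(grid, commodities=("c",))
        ledger = ledger_from(
            pd.DataFrame({2050: [0.0]}, index=pd.Index(["c"], name="commodity")),
            base,
        )
        prod = pd.DataFrame({2050: [10.0]}, index=pd.Index(["c"], name="commodity"))
        rep = gap_report(ledger, prod)
        assert rep.cells.loc[("c", 2050), "gap"] == 0.0
        assert rep.cells.loc[("c", 2050), "gap_share"] == 0.0

    def test_aggregate_equals_brute_force_sum(self, grid):
        rng = np.random.default_rng(7)
        names = [f"c{i}" for i in range(6)]
        base = make_baseline(grid, commodities=names)
        targets = pd.DataFrame(
            {2050: rng.uniform(50, 200, 6)}, index=pd.Index(names, name="commodity")
        )
        prod = pd.DataFrame(
            {2050: rng.uniform(20, 250, 6)}, index=pd.Index(names, name="commodity")
        )
        rep = gap_report(ledger_from(targets, base), prod)
        brute = sum(
            max(0.0, targets.loc[c, 2050] - prod.loc[c, 2050]) for c in names
        )
        assert rep.totals.loc[2050, "gap"] == pytest.approx(brute)

    def test_gap_monotone_under_dominating_shifters(self, bundle, bau_result,
                                                    combined_result):
        """A scenario whose shifters dominate BAU pointwise never has a
        larger gap in any cell."""
        g_bau = bau_result.gaps.cells["gap"]
        g_scn = combined_result.gaps.cells["gap"]
        assert (g_scn <= g_bau + 1e-9).all()

    def test_rounded_view_uses_percent_and_thousand_tonnes(self, bau_result):
        view = bau_result.gaps.rounded()
        assert (view["gap_share"] == view["gap_share"].round()).all()
        assert (view["gap"] % 1000 == 0).all()


class TestScenarioDelta:
    def test_identical_scenarios_zero_delta(self, bau_result):
        delta = scenario_delta(bau_result.gaps, bau_result.gaps)
        assert np.allclose(delta["delta_tonnes"], 0.0)

    def test_mismatched_targets_rejected(self, grid, bau_result):
        base = make_baseline(grid, commodities=("c",))
        other = gap_report(
            ledger_from(
                pd.DataFrame({y: [1.0] for y in grid.projection_years},
                             index=pd.Index(["c"], name="commodity")),
                base,
            ),
            pd.DataFrame({y: [1.0] for y in grid.projection_years},
                         index=pd.Index(["c"], name="commodity")),
        )
        with pytest.raises(ValidationError):
            scenario_delta(bau_result.gaps, other)

    def test_combined_gain_exceeds_sum_of_parts(self, bundle, bau_result):
        """Multiplicative composition: the combined scenario adds at least as
        much production as the single scenarios together."""
        from foodsys.pipeline import PathwayConfig, run_pathway

        cca = run_pathway(PathwayConfig(management="CCA"), bundle)
        boost = run_pathway(PathwayConfig(management="BOOST"), bundle)
        both = run_pathway(PathwayConfig(management="CCA_BOOST"), bundle)
        d_cca = scenario_delta(bau_result.gaps, cca.gaps)["delta_tonnes"]
        d_boost = scenario_delta(bau_result.gaps, boost.gaps)["delta_tonnes"]
        d_both = scenario_delta(bau_result.gaps, both.gaps)["delta_tonnes"]
        assert (d_both >= d_cca + d_boost - 1e-6).all()


class TestCalorieAvailability:
    def test_unit_check_1000_kcal_per_day(self, grid):
        pop = PopulationTrajectory("SSP2", pd.Series({2020: 1_000_000.0}))
        supply = pd.DataFrame({2020: [365_000.0]},
                              index=pd.Index(["grain"], name="commodity"))
        rep = calorie_availability(supply, pop, {"grain": 1.0e6})
        assert rep.kcal_per_capita_day.loc[2020] == pytest.approx(1000.0)

    def test_zero_supply_zero_calories(self, grid):
        pop = PopulationTrajectory("SSP2", pd.Series({2020: 1e6}))
        supply = pd.DataFrame({2020: [0.0]},
                              index=pd.Index(["grain"], name="commodity"))
        rep = calorie_availability(supply, pop, {"grain": 1.0e6})
        assert rep.kcal_per_capita_day.loc[2020] == 0.0

    def test_missing_energy_factor_names_commodity(self, grid):
        pop = PopulationTrajectory("SSP2", pd.Series({2020: 1e6}))
        supply = pd.DataFrame({2020: [10.0]},
                              index=pd.Index(["mystery"], name="commodity"))
        with pytest.raises(ValidationError, match="mystery"):
            calorie_availability(supply, pop, {})

    def test_linear_in_supply_inverse_in_population(self, grid):
        pop1 = PopulationTrajectory("SSP2", pd.Series({2020: 1e6}))
        pop2 = PopulationTrajectory("SSP2", pd.Series({2020: 2e6}))
        supply = pd.DataFrame({2020: [100_000.0]},
                              index=pd.Index(["grain"], name="commodity"))
        r1 = calorie_availability(supply, pop1, {"grain": 2.0e6})
        r2 = calorie_availability(supply * 2, pop1, {"grain": 2.0e6})
        r3 = calorie_availability(supply, pop2, {"grain": 2.0e6})
        assert r2.kcal_per_capita_day.loc[2020] == pytest.approx(
            2 * r1.kcal_per_capita_day.loc[2020]
        )
        assert r3.kcal_per_capita_day.loc[2020] == pytest.approx(
            r1.kcal_per_capita_day.loc[2020] / 2
        )

    def test_fixture_baseline_diet_supplies_2553_kcal(self, bundle, fixture_baseline):
        level = fixture_baseline.kcal_per_capita_day(bundle.kcal_per_tonne)
        assert level == pytest.approx(2553.0, abs=1e-6)
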