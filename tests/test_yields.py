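"""Yield shifters: adaptation, intensification, composition, production."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from foodsys.core import CropParams, TimeGrid, ValidationError
from foodsys.yields import (
    ClimateShifter,
    ManagementScenario,
    boost_path,
    boost_target_yield,
    cca_multiplier,
    compose_shifters,
    feasible_production,
)


def crop(name="millet", area=100_000.0, yld=1.0, pot=3.0, hist=1.2):
    return CropParams(commodity=name, area_base=area, yield_base=yld,
                      yield_potential=pot, yield_hist_max=hist,
                      kcal_per_tonne=3.4e6)


CCA = ManagementScenario("CCA")
BOOST = ManagementScenario("BOOST")
BOTH = ManagementScenario("CCA_BOOST")
BAU = ManagementScenario("BAU")


class TestCcaMultiplier:
    def test_full_adoption_gain_on_focus_crop(self):
        assert cca_multiplier(CCA, "millet", 2050) == pytest.approx(1.13)

    def test_non_focus_commodity_unchanged(self):
        assert cca_multiplier(CCA, "milk", 2050) == 1.0

    def test_half_adoption_scales_linearly(self):
        assert cca_multiplier(CCA, "millet", 2025) == pytest.approx(1.065)

    def test_bau_has_no_adaptation_effect(self):
        assert cca_multiplier(BAU, "millet", 2050) == 1.0

    def test_adoption_zero_before_ramp(self):
        assert cca_multiplier(CCA, "millet", 2015) == 1.0


class TestBoostTarget:
    @pytest.mark.parametrize(
        "pot, hist, expected",
        [
            (4.0, 1.2, 3.0),  # 75% of potential when history is below it
            (1.0, 0.9, 0.9),  # historical max already above 75% of potential
            (1.0, 0.75, 0.75),  # boundary tie: both readings coincide
        ],
    )
    def test_target_is_fraction_of_potential_or_historical_max(
        self, pot, hist, expected
    ):
        p = crop(yld=0.5, pot=pot, hist=hist)
        assert boost_target_yield(p, BOOST) == pytest.approx(expected)

    def test_target_never_below_base_yield(self):
        p = crop(yld=0.95, pot=1.0, hist=0.9)
        assert boost_target_yield(p, BOOST) == pytest.approx(0.95)

    def test_missing_potential_names_crop(self):
        p = crop(name="cassava", pot=0.0)
        with pytest.raises(ValidationError, match="cassava"):
            boost_target_yield(p, BOOST)


class TestBoostPath:
    def test_linear_ramp_midpoint(self, grid):
        p = crop(yld=1.0)
        path = boost_path(p, target=3.0, grid=grid, ramp_start=2020)
        assert path.loc[2035] == pytest.approx(2.0)  # yield t/ha via x1 base
        assert path.loc[2050] == pytest.approx(3.0)
        assert path.loc[2020] == 1.0

    def test_target_equal_base_is_identity(self, grid):
        p = crop(yld=1.5)
        path = boost_path(p, target=1.5, grid=grid)
        assert (path == 1.0).all()

    def test_target_below_base_floored_with_warning(self, grid):
        p = crop(yld=2.0)
        with pytest.warns(UserWarning, match="floored"):
            path = boost_path(p, target=1.0, grid=grid)
        assert (path >= 1.0).all()

    @given(base=st.floats(0.5, 5.0), target_ratio=st.floats(1.0, 5.0))
    def test_constant_per_step_increment(self, base, target_ratio):
        """Finite differences of the ramp are constant (linear growth)."""
        grid = TimeGrid()
        p = crop(yld=base)
        path = boost_path(p, target=base * target_ratio, grid=grid)
        yields = path * base
        ramp = yields.loc[2020:]
        diffs = np.diff(ramp.to_numpy())
        assert np.allclose(diffs, diffs[0], atol=1e-9 * base)


class TestCompose:
    def test_sequential_multipliers_not_additive(self, grid):
        """+8% adaptation and +40% intensification combine to +51.2%,
        not +48%: shifters multiply."""
        combined = 1.08 * 1.40
        assert combined == pytest.approx(1.512)
        assert round((combined - 1) * 100) == 51

    def test_identity_composition(self, grid):
        params = {"millet": crop()}
        composed = compose_shifters(None, BAU, params, grid)
        assert np.allclose(composed.to_numpy(), 1.0)

    def test_bau_reduces_to_climate_alone(self, grid):
        years = list(grid.projection_years)
        span = grid.end_year - grid.projection_start
        frame = pd.DataFrame(
            {y: 1.0 - 0.05 * (y - 2015) / span for y in years},
            index=pd.Index(["millet"], name="crop"),
        )
        climate = ClimateShifter("RCP6.0", False, frame)
        composed = compose_shifters(climate, BAU, {"millet": crop()}, grid)
        pd.testing.assert_frame_equal(
            composed, frame, check_names=False, check_column_type=False
        )

    def test_mismatched_crop_sets_error_lists_difference(self, grid):
        frame = pd.DataFrame({y: 1.0 for y in grid.projection_years},
                             index=pd.Index(["maize"], name="crop"))
        climate = ClimateShifter("RCP2.6", True, frame)
        with pytest.raises(ValidationError, match="maize"):
            compose_shifters(climate, BAU, {"millet": crop()}, grid)

    @given(
        m1=st.lists(st.floats(0.5, 2.0), min_size=8, max_size=8),
        m2=st.lists(st.floats(0.5, 2.0), min_size=8, max_size=8),
    )
    def test_product_matches_log_space_oracle(self, m1, m2):
        """Pointwise product equals exp(sum of logs), order-independent."""
        a, b = np.array(m1), np.array(m2)
        assert np.allclose(a * b, np.exp(np.log(a) + np.log(b)))
        assert np.allclose(a * b, b * a)

    def test_composed_combined_scenario_is_product_of_parts(self, grid):
        params = {"millet": crop(), "rice": crop("rice", 50_000, 0.8, 3.2, 1.2)}
        years = list(grid.projection_years)
        frame = pd.DataFrame({y: 0.97 for y in years},
                             index=pd.Index(list(params), name="crop"))
        frame[2015] = 1.0
        climate = ClimateShifter("RCP2.6", True, frame)
        c_only = compose_shifters(climate, BAU, params, grid)
        cca_only = compose_shifters(None, CCA, params, grid)
        boost_only = compose_shifters(None, BOOST, params, grid)
        both = compose_shifters(climate, BOTH, params, grid)
        pd.testing.assert_frame_equal(both, c_only * cca_only * boost_only)


class TestFeasibleProduction:
    def test_area_times_yield_times_shifter(self, grid):
        params = {"millet": crop(area=100_000.0, yld=1.0)}
        shifters = pd.DataFrame({y: 0.95 for y in grid.projection_years},
                                index=pd.Index(["millet"], name="crop"))
        prod = feasible_production(params, shifters, grid=grid)
        assert prod.loc["millet", 2050] == pytest.approx(95_000.0)

    def test_boost_endpoint_exactness(self, grid):
        """2050 production under Boost equals area x target yield exactly."""
        p = crop(yld=1.0, pot=3.0, hist=1.2)
        target = boost_target_yield(p, BOOST)
        shifters = compose_shifters(None, BOOST, {"millet": p}, grid)
        prod = feasible_production({"millet": p}, shifters, grid=grid)
        assert prod.loc["millet", 2050] == pytest.approx(p.area_base * target, rel=1e-12)

    def test_monotone_in_management_intensity(self, grid):
        p = {"millet": crop()}
        for weak, strong in [
            (ManagementScenario("CCA", cca_gain=0.05),
             ManagementScenario("CCA", cca_gain=0.13)),
            (ManagementScenario("BOOST", boost_fraction=0.5),
             ManagementScenario("BOOST", boost_fraction=0.75)),
        ]:
            lo = feasible_production(p, compose_shifters(None, weak, p, grid), grid=grid)
            hi = feasible_production(p, compose_shifters(None, strong, p, grid), grid=grid)
            assert (hi.to_numpy() >= lo.to_numpy() - 1e-12).all()

    def test_boost_never_reduces_yields_below_base(self, grid):
        p = {"millet": crop(yld=2.0, pot=1.0, hist=0.5)}  # 75% of potential < base
        composed = compose_shifters(None, BOOST, p, grid)
        assert (composed.to_numpy() >= 1.0 - 1e-12).all()

    def test_non_crop_commodities_frozen_at_calibration_mean(
        self, bundle, fixture_baseline, grid
    ):
        shifters = compose_shifters(None, BAU, bundle.crop_params, grid)
        prod = feasible_production(bundle.crop_params, shifters, fixture_baseline, grid)
        assert prod.loc["milk", 2050] == pytest.approx(
            fixture_baseline.production_base["milk"]
        )
        assert prod.loc["milk", 2015] == prod.loc["milk", 2050]
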