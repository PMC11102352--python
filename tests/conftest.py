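import pandas as pd
import pytest
from hypothesis import settings

from foodsys.core import Baseline, BalanceSheet, TimeGrid, calibrate_baseline
from foodsys.pipeline import PathwayConfig, run_pathway
from foodsys.synth import gambia_fixture

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def bundle():
    return gambia_fixture()


@pytest.fixture(scope="session")
def fixture_baseline(bundle):
    pop = bundle.populations["SSP2"]
    return calibrate_baseline(bundle.balance_sheet, pop.values.to_dict(), bundle.grid)


@pytest.fixture(scope="session")
def bau_result(bundle):
    return run_pathway(PathwayConfig(management="BAU"), bundle)


@pytest.fixture(scope="session")
def combined_result(bundle):
    return run_pathway(PathwayConfig(management="CCA_BOOST"), bundle)


def toy_balance_sheet(commodities=("rice", "millet", "milk"), years=range(2000, 2011),
                      production=100.0, imports=20.0, exports=5.0) -> BalanceSheet:
    """Constant-year toy ledger with a consistent supply identity."""
    records = []
    for c in commodities:
        supply = production + imports - exports
        for y in years:
            records += [
                (c, y, "production", production),
                (c, y, "imports", imports),
                (c, y, "exports", exports),
                (c, y, "food", supply * 0.8),
                (c, y, "feed", supply * 0.1),
                (c, y, "seed", supply * 0.05),
                (c, y, "waste", supply * 0.05),
                (c, y, "other", 0.0),
            ]
    return BalanceSheet(pd.DataFrame(records, columns=BalanceSheet.COLUMNS))


@pytest.fixture
def toy_bs() -> BalanceSheet:
    return toy_balance_sheet()


def constant_population(grid: TimeGrid, persons: float = 1e6) -> dict[int, float]:
    return {y: persons for y in grid.years}
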