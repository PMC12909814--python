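import numpy as np
import pandas as pd
import pytest

import cobenefits as cb


@pytest.fixture(scope="session")
def world():
    """Default-size synthetic world shared (read-only) across tests."""
    return cb.generate_world(cb.WorldConfig(seed=7))


@pytest.fixture(scope="session")
def scenario_pair(world):
    """(baseline, mitigation) scenarios on the shared world."""
    scens = cb.generate_scenarios(
        world.grid, world.masks, world.config,
        [cb.ScenarioSpec("baseline"), cb.ScenarioSpec("mit40", 0.40)],
    )
    return scens[0], scens[1]


def make_binary_masks(grid, cells_by_country, table=None):
    """Masks with whole-cell (fraction 1) territories from explicit cells.

    ``cells_by_country`` maps country_id -> list of (i, j) cells.
    """
    ids = list(cells_by_country)
    fractions = np.zeros((len(ids),) + grid.shape)
    for c, cid in enumerate(ids):
        for i, j in cells_by_country[cid]:
            fractions[c, i, j] = 1.0
    if table is None:
        table = pd.DataFrame(
            {
                "country_id": ids,
                "name": ids,
                "region": ["R0"] * len(ids),
                "hdi": np.linspace(0.4, 0.9, len(ids)),
                "gdp_rank": np.arange(1, len(ids) + 1),
            }
        )
    return cb.CountryMaskSet(grid=grid, fractions=fractions, table=table)


def make_linear_risk_model(countries, slope=0.01, y0=0.01, pop=1e6,
                           max_exposure=500.0):
    """Risk model with one outcome/age and a single linear RR segment.

    RR(z) = 1 + slope * z from 0 to ``max_exposure``, identical across
    bounds, for every listed country.
    """
    curve = cb.RRCurve(
        exposures=np.array([0.0, max_exposure]),
        rr=np.array([1.0, 1.0 + slope * max_exposure]),
    )
    curves = {("ihd", "all", b): curve for b in ("lower", "central", "upper")}
    rates = pd.DataFrame(
        [
            {"country_id": c, "outcome": "ihd", "age_group": "all",
             "bound": b, "y0": y0}
            for c in countries for b in ("lower", "central", "upper")
        ]
    )
    population = pd.DataFrame(
        [{"country_id": c, "age_group": "all", "pop": pop} for c in countries]
    )
    return cb.RiskModel(curves=curves, rates=rates, population=population,
                        tmrel=0.0)
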