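import numpy as np
import pandas as pd
import pytest

import cobenefits as cb
from cobenefits.health import BOUNDS

from conftest import make_linear_risk_model


@pytest.fixture
def simple_curve():
    return cb.RRCurve(
        exposures=np.array([5.0, 10.0, 20.0]), rr=np.array([1.0, 1.2, 1.4])
    )


class TestRelativeRisk:
    def test_below_tmrel_is_one(self, simple_curve):
        assert cb.relative_risk(0.0, simple_curve) == 1.0
        assert cb.relative_risk(5.0, simple_curve) == 1.0

    def test_breakpoint_returns_tabulated_value(self, simple_curve):
        assert cb.relative_risk(10.0, simple_curve) == pytest.approx(1.2)

    def test_midpoint_interpolates_linearly(self, simple_curve):
        assert cb.relative_risk(15.0, simple_curve) == pytest.approx(1.3)

    def test_constant_beyond_last_breakpoint(self, simple_curve):
        assert cb.relative_risk(500.0, simple_curve) == pytest.approx(1.4)

    def test_nonmonotone_curve_rejected(self):
        with pytest.raises(cb.ValidationError):
            cb.RRCurve(exposures=np.array([0.0, 5.0, 10.0]),
                       rr=np.array([1.0, 1.5, 1.2]))

    def test_rr_below_one_rejected(self):
        with pytest.raises(cb.ValidationError):
            cb.RRCurve(exposures=np.array([0.0, 5.0]), rr=np.array([0.9, 1.2]))


class TestMortality:
    def test_zero_at_and_below_tmrel(self):
        model = make_linear_risk_model(["A"])
        curve = cb.RRCurve(np.array([10.0, 50.0]), np.array([1.0, 2.0]))
        model.curves = {("ihd", "all", b): curve for b in BOUNDS}
        model._terms_cache.clear()
        assert cb.mortality(10.0, model, "A") == 0.0
        assert cb.mortality(3.0, model, "A") == 0.0

    def test_hand_evaluated_attributable_fraction(self):
        # y0 = 0.01 / yr, RR = 1.25, pop = 1e6 -> 0.01 * (1 - 0.8) * 1e6
        model = make_linear_risk_model(["A"], slope=0.25 / 10.0, y0=0.01, pop=1e6)
        assert cb.mortality(10.0, model, "A") == pytest.approx(2000.0, rel=1e-12)

    def test_saturates_at_total_baseline_deaths(self):
        model = make_linear_risk_model(["A"], slope=1e6, y0=0.01, pop=1e6)
        assert cb.mortality(400.0, model, "A") == pytest.approx(
            0.01 * 1e6, rel=1e-6
        )

    def test_nondecreasing_and_continuous_in_exposure(self, world):
        model = world.risk_model
        country = world.masks.country_ids[0]
        z = np.linspace(0, 200, 400)
        m = cb.mortality(z, model, country)
        assert np.all(np.diff(m) >= -1e-9)
        # continuity across a breakpoint
        eps = 1e-7
        for bp in (model.tmrel + 5.0, model.tmrel + 10.0):
            assert cb.mortality(bp + eps, model, country) == pytest.approx(
                cb.mortality(bp - eps, model, country), rel=1e-6
            )

    def test_missing_country_rejected(self, world):
        with pytest.raises(cb.ValidationError):
            cb.mortality(10.0, world.risk_model, "nowhere")


def _contribution(grid, receptors, values):
    return cb.ExposureContribution(
        receptors=receptors, values=values, grid=grid,
        scenario_id="mit", baseline_id="baseline",
    )


class TestDeathsAvoided:
    def test_zero_cells_give_exact_zero(self, world, scenario_pair):
        base, mit = scenario_pair
        dj = cb.attribute_exposure(world.sensitivities, cb.scenario_delta(mit, base))
        deaths = cb.deaths_avoided(dj, world.baseline_exposure, world.risk_model)
        assert np.all(deaths.values[dj.values == 0.0] == 0.0)

    def test_reductions_give_positive_cobenefits(self, world, scenario_pair):
        base, mit = scenario_pair
        dj = cb.attribute_exposure(world.sensitivities, cb.scenario_delta(mit, base))
        deaths = cb.deaths_avoided(dj, world.baseline_exposure, world.risk_model)
        assert np.all(deaths.values[dj.values < 0] > 0)

    def test_linear_segment_matches_analytic_closed_form(self):
        """On a single linear RR segment the per-cell difference has the
        closed form y0*pop*(1/RR(J+dJ) - 1/RR(J)); cellwise deaths summed
        must match it to 1e-8 relative."""
        grid = cb.Grid.regular(2, 3)
        slope, y0, pop, jm = 0.02, 0.01, 1e6, 50.0
        model = make_linear_risk_model(["A"], slope=slope, y0=y0, pop=pop)
        rng = np.random.default_rng(9)
        dvals = -rng.uniform(0.01, 0.5, (1,) + grid.shape)
        dj = _contribution(grid, ["A"], dvals)
        deaths = cb.deaths_avoided(dj, {"A": jm}, model)

        def rr(z):
            return 1.0 + slope * z

        expected = y0 * pop * (1.0 / rr(jm + dvals[0]) - 1.0 / rr(jm))
        assert np.allclose(deaths.values[0], expected, rtol=1e-8)

    def test_exposure_clamped_at_zero_with_warning(self, caplog):
        grid = cb.Grid.regular(2, 2)
        model = make_linear_risk_model(["A"])
        dvals = np.zeros((1,) + grid.shape)
        dvals[0, 0, 0] = -50.0  # larger than the 10 ug/m3 baseline
        dj = _contribution(grid, ["A"], dvals)
        with caplog.at_level("WARNING", logger="cobenefits.health"):
            deaths = cb.deaths_avoided(dj, {"A": 10.0}, model)
        assert "clamped" in caplog.text
        # clamping caps the benefit at the full attributable burden
        assert deaths.values[0, 0, 0] == pytest.approx(
            cb.mortality(10.0, model, "A"), rel=1e-12
        )

    def test_missing_receptor_exposure_rejected(self, world):
        dj = _contribution(world.grid, ["ghost"], np.zeros((1,) + world.grid.shape))
        with pytest.raises(cb.ValidationError):
            cb.deaths_avoided(dj, world.baseline_exposure, world.risk_model)


class TestJointAndUncertainty:
    def test_marginal_sum_near_joint_for_small_perturbations(self, world, scenario_pair):
        base, mit = scenario_pair
        dj = cb.attribute_exposure(world.sensitivities, cb.scenario_delta(mit, base))
        # scale so each receptor's total perturbation is ~0.1% of baseline
        scale = min(
            0.001 * world.baseline_exposure[r] / max(abs(dj.values[i].sum()), 1e-30)
            for i, r in enumerate(dj.receptors)
        )
        small = _contribution(world.grid, dj.receptors, dj.values * scale)
        frame = cb.nonadditivity(small, world.baseline_exposure, world.risk_model)
        rel = (frame["residual"].abs() / frame["joint"].abs()).max()
        assert rel < 5e-3

    def test_degenerate_bounds_identical(self, world, scenario_pair):
        base, mit = scenario_pair
        dj = cb.attribute_exposure(world.sensitivities, cb.scenario_delta(mit, base))
        model = make_linear_risk_model(list(world.baseline_exposure.index))
        passes = cb.uncertainty_passes(dj, world.baseline_exposure, model)
        assert np.array_equal(passes["lower"].values, passes["central"].values)
        assert np.array_equal(passes["central"].values, passes["upper"].values)

    def test_ordered_bounds_give_ordered_totals(self, world, scenario_pair):
        base, mit = scenario_pair
        dj = cb.attribute_exposure(world.sensitivities, cb.scenario_delta(mit, base))
        passes = cb.uncertainty_passes(dj, world.baseline_exposure, world.risk_model)
        for receptor in dj.receptors:
            lo = passes["lower"].receptor_total(receptor)
            mid = passes["central"].receptor_total(receptor)
            hi = passes["upper"].receptor_total(receptor)
            assert lo <= mid + 1e-12
            assert mid <= hi + 1e-12

    def test_missing_bound_falls_back_to_central_with_warning(self, world, scenario_pair):
        base, mit = scenario_pair
        dj = cb.attribute_exposure(world.sensitivities, cb.scenario_delta(mit, base))
        model = world.risk_model
        stripped = cb.RiskModel(
            curves=model.curves,
            rates=model.rates[model.rates["bound"] != "upper"].reset_index(drop=True),
            population=model.population,
            tmrel=model.tmrel,
        )
        with pytest.warns(UserWarning, match="using central"):
            passes = cb.uncertainty_passes(dj, world.baseline_exposure, stripped)
        assert np.array_equal(passes["upper"].values, passes["central"].values)
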