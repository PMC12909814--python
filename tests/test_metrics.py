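import numpy as np
import pandas as pd
import pytest

import cobenefits as cb
from cobenefits.metrics import FLAG_OK, FLAG_UNDEFINED

from conftest import make_binary_masks


def _cellwise(grid, receptors, values):
    return cb.MortalityContribution(
        receptors=receptors, values=values, grid=grid,
        scenario_id="mit", baseline_id="baseline",
    )


@pytest.fixture
def two_country_setup():
    grid = cb.Grid.regular(2, 4)
    masks = make_binary_masks(
        grid, {"A": [(0, 0), (0, 1)], "B": [(1, 2), (1, 3)]}
    )
    return grid, masks


class TestTransboundaryFraction:
    def test_all_internal_gives_zero(self, two_country_setup):
        grid, masks = two_country_setup
        values = np.zeros((1,) + grid.shape)
        values[0, 0, 0] = 70.0
        values[0, 0, 1] = 30.0
        tf, flag = cb.transboundary_fraction(
            _cellwise(grid, ["A"], values), masks, "A"
        )
        assert tf == pytest.approx(0.0, abs=1e-15)
        assert flag == FLAG_OK

    def test_all_external_gives_one(self, two_country_setup):
        grid, masks = two_country_setup
        values = np.zeros((1,) + grid.shape)
        values[0, 1, 2] = 100.0  # entirely inside B, external to A
        tf, flag = cb.transboundary_fraction(
            _cellwise(grid, ["A"], values), masks, "A"
        )
        assert tf == pytest.approx(1.0)
        assert flag == FLAG_OK

    def test_planted_thirty_of_hundred(self, two_country_setup):
        grid, masks = two_country_setup
        values = np.zeros((1,) + grid.shape)
        values[0, 0, 0] = 70.0   # domestic
        values[0, 1, 3] = 30.0   # external (in B)
        tf, _ = cb.transboundary_fraction(_cellwise(grid, ["A"], values), masks, "A")
        assert tf == pytest.approx(0.30, rel=1e-12)

    def test_zero_total_flagged_undefined(self, two_country_setup):
        grid, masks = two_country_setup
        tf, flag = cb.transboundary_fraction(
            _cellwise(grid, ["A"], np.zeros((1,) + grid.shape)), masks, "A"
        )
        assert np.isnan(tf)
        assert flag == FLAG_UNDEFINED

    def test_group_tf_is_weighted_not_mean(self, two_country_setup):
        """Group TF must equal sum(external)/sum(total) over members, which
        differs from the mean of member TFs when totals differ."""
        grid, masks = two_country_setup
        values = np.zeros((2,) + grid.shape)
        # receptor A: 90 domestic, 10 from B => TF 0.1, total 100
        values[0, 0, 0] = 90.0
        values[0, 1, 2] = 10.0
        # receptor B: 1 domestic, 9 from A => TF 0.9, total 10
        values[1, 1, 2] = 1.0
        values[1, 0, 0] = 9.0
        contrib = _cellwise(grid, ["A", "B"], values)
        group_tf, _ = cb.transboundary_fraction(contrib, masks, ["A", "B"])
        # intra-group cross contributions count as internal => group TF 0
        assert group_tf == pytest.approx(0.0, abs=1e-15)
        # single-country TFs unchanged
        assert cb.transboundary_fraction(contrib, masks, "A")[0] == pytest.approx(0.1)
        assert cb.transboundary_fraction(contrib, masks, "B")[0] == pytest.approx(0.9)

    def test_global_tf_weighted_identity(self, world, scenario_pair):
        base, mit = scenario_pair
        dj = cb.attribute_exposure(world.sensitivities, cb.scenario_delta(mit, base))
        deaths = cb.deaths_avoided(dj, world.baseline_exposure, world.risk_model)
        table = cb.tf_table(deaths, world.masks)
        expected = table["external"].sum() / table["total"].sum()
        assert cb.global_tf(deaths, world.masks) == pytest.approx(expected, rel=1e-12)
        assert 0 <= cb.mean_country_tf(deaths, world.masks) <= 1

    def test_unknown_receptor_rejected(self, two_country_setup):
        grid, masks = two_country_setup
        contrib = _cellwise(grid, ["A"], np.zeros((1,) + grid.shape))
        with pytest.raises(cb.ValidationError):
            cb.transboundary_fraction(contrib, masks, "Z")


@pytest.fixture
def planted_matrix():
    values = pd.DataFrame(
        {
            "A": [50.0, 25.0, 0.0],
            "B": [40.0, 10.0, 5.0],
        },
        index=["A", "B", cb.UNATTRIBUTED],
    )
    return cb.ContributionMatrix(values=values, quantity="deaths")


class TestExchange:
    def test_lone_source_zero_reverse_exchange(self, two_country_setup):
        grid, masks = two_country_setup
        values = np.zeros((2,) + grid.shape)
        values[0, 0, 0] = 5.0  # receptor A benefits from its own cell
        values[1, 0, 0] = 3.0  # receptor B benefits from A's cell
        matrix = cb.aggregate_sources(_cellwise(grid, ["A", "B"], values), masks,
                                      quantity="deaths")
        assert cb.exchange(matrix, "B", "A") == 0.0
        assert cb.exchange(matrix, "A", "B") == pytest.approx(3.0)

    def test_column_sum_plus_unattributed_is_receptor_total(self, planted_matrix):
        for receptor in ("A", "B"):
            col = sum(
                cb.exchange(planted_matrix, s, receptor)
                for s in planted_matrix.sources
            )
            assert col == pytest.approx(planted_matrix.receptor_total(receptor))

    def test_planted_net_exchange(self, planted_matrix):
        # EXC(A,B)=40, EXC(B,A)=25 -> net 15
        assert cb.net_exchange(planted_matrix, "A", "B") == pytest.approx(15.0)

    def test_net_exchange_antisymmetric(self, planted_matrix):
        assert cb.net_exchange(planted_matrix, "A", "B") == -cb.net_exchange(
            planted_matrix, "B", "A"
        )

    def test_unknown_country_rejected(self, planted_matrix):
        with pytest.raises(cb.ValidationError):
            cb.exchange(planted_matrix, "Z", "A")


class TestTEC:
    def test_balanced_exchange_is_half(self):
        values = pd.DataFrame({"A": [0.0, 7.0], "B": [7.0, 0.0]}, index=["A", "B"])
        matrix = cb.ContributionMatrix(values=values)
        assert cb.tec(matrix, "A", "B")[0] == 0.5

    def test_ninety_ten_split(self):
        values = pd.DataFrame({"A": [0.0, 10.0], "B": [90.0, 0.0]}, index=["A", "B"])
        matrix = cb.ContributionMatrix(values=values)
        assert cb.tec(matrix, "A", "B")[0] == pytest.approx(0.9)

    def test_complement_identity_exact(self, planted_matrix):
        a, _ = cb.tec(planted_matrix, "A", "B")
        b, _ = cb.tec(planted_matrix, "B", "A")
        assert a + b == 1.0  # exact, not approximate

    def test_zero_gross_exchange_flagged(self):
        values = pd.DataFrame({"A": [0.0, 0.0], "B": [0.0, 0.0]}, index=["A", "B"])
        matrix = cb.ContributionMatrix(values=values)
        t, flag = cb.tec(matrix, "A", "B")
        assert np.isnan(t)
        assert flag == FLAG_UNDEFINED

    def test_self_pair_rejected(self, planted_matrix):
        with pytest.raises(cb.ValidationError):
            cb.tec(planted_matrix, "A", "A")

    def test_exchange_table_excludes_diagonal_and_unattributed(self, planted_matrix):
        table = cb.exchange_table(planted_matrix)
        assert not (table["source"] == table["receptor"]).any()
        assert cb.UNATTRIBUTED not in set(table["source"])
        assert len(table) == 2


class TestStratifiedSummary:
    def test_constant_field_equal_means(self):
        tf = pd.Series(0.4, index=[f"C{i}" for i in range(6)])
        strata = pd.Series(np.arange(6) / 10, index=tf.index)
        out = cb.stratified_summary(tf, strata, k=2)
        assert out.loc["bottom_2", "mean_tf"] == out.loc["top_2", "mean_tf"] == 0.4

    def test_planted_two_stratum_means(self):
        tf = pd.Series([0.8, 0.7, 0.2, 0.1], index=["p", "q", "r", "s"])
        hdi = pd.Series([0.3, 0.4, 0.8, 0.9], index=["p", "q", "r", "s"])
        out = cb.stratified_summary(tf, hdi, k=2)
        assert out.loc["bottom_2", "mean_tf"] == pytest.approx(0.75)
        assert out.loc["top_2", "mean_tf"] == pytest.approx(0.15)
        assert out.loc["bottom_2", "members"] == "p,q"

    def test_tie_broken_by_country_id(self):
        tf = pd.Series([0.1, 0.2, 0.3], index=["c", "a", "b"])
        strata = pd.Series([0.5, 0.5, 0.5], index=["c", "a", "b"])
        out = cb.stratified_summary(tf, strata, k=1)
        assert out.loc["bottom_1", "members"] == "a"
        assert out.loc["top_1", "members"] == "c"

    def test_oversized_k_rejected(self):
        tf = pd.Series([0.1], index=["a"])
        with pytest.raises(cb.ValidationError):
            cb.stratified_summary(tf, tf, k=2)
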