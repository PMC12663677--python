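import numpy as np
import pytest

from tercab.geodetector import (InteractionReport, classify_interaction,
                                discretize, factor_report, interaction_q,
                                overlay_strata, q_statistic)
from tercab.gridio import Grid


def _brute_force_q(y, strata):
    """Independent group-by variance decomposition oracle."""
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    n = y.size
    total = n * y.var()  # population variance
    within = sum(np.sum(strata == s) * y[strata == s].var()
                 for s in np.unique(strata))
    return 1.0 - within / total


class TestQStatistic:
    def test_single_stratum_zero(self):
        assert q_statistic([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_perfect_separation_one(self):
        assert q_statistic([1.0, 1.0, 2.0, 2.0], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # within-SS 4*0.25, total-SS 4*1.25 -> q = 0.8
        assert q_statistic([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1]) == pytest.approx(0.8)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            y = rng.normal(size=50)
            strata = rng.integers(0, 5, size=50)
            assert q_statistic(y, strata) == pytest.approx(
                _brute_force_q(y, strata), abs=1e-12)

    def test_relabel_invariance(self, rng):
        y = rng.normal(size=40)
        strata = rng.integers(0, 4, size=40)
        relabeled = (strata * 7 + 3) % 11  # injective remap
        assert q_statistic(y, strata) == pytest.approx(
            q_statistic(y, relabeled), abs=1e-14)

    def test_q_in_unit_interval(self, rng):
        for _ in range(50):
            y = rng.normal(size=30)
            strata = rng.integers(0, 6, size=30)
            q = q_statistic(y, strata)
            assert 0.0 <= q <= 1.0 + 1e-12

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(q_statistic([2.0, 2.0, 2.0], [0, 1, 1]))

    def test_invalid_cells_dropped(self):
        q_full = q_statistic([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        q_masked = q_statistic([1.0, 2.0, 3.0, 4.0, np.nan, 9.0],
                               [0, 0, 1, 1, 0, -1])
        assert q_masked == pytest.approx(q_full)


class TestDiscretize:
    def test_categorical_passthrough(self):
        codes = np.array([[3, 1], [7, 1]], dtype=float)
        labels = discretize(codes, categorical=True)
        np.testing.assert_array_equal(labels, [3, 1, 7, 1])

    def test_quantile_equal_bins(self):
        labels = discretize(np.arange(1.0, 101.0), k=5)
        counts = np.bincount(labels)
        np.testing.assert_array_equal(counts, [20] * 5)

    def test_skewed_quantile_counts_balanced(self, rng):
        vals = np.exp(rng.normal(size=200))
        labels = discretize(vals, k=4)
        counts = np.bincount(labels)
        assert (np.abs(counts - 50) <= 1).all()

    def test_equal_interval(self):
        labels = discretize(np.array([0.0, 0.1, 5.0, 9.9, 10.0]), k=2,
                            method="equal-interval")
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1])

    def test_too_few_distinct_values_reduces_k(self):
        with pytest.warns(UserWarning, match="reducing k"):
            labels = discretize(np.array([1.0, 1.0, 2.0, 2.0]), k=5)
        assert len(np.unique(labels)) <= 2

    def test_nan_marked_invalid(self):
        labels = discretize(np.array([1.0, np.nan, 3.0, 4.0]), k=2)
        assert labels[1] == -1

    def test_grid_input_accepted(self):
        g = Grid(np.arange(16, dtype=float).reshape(4, 4))
        labels = discretize(g, k=4)
        assert labels.shape == (16,)

    def test_bad_method_raises(self):
        with pytest.raises(ValueError, match="method"):
            discretize(np.arange(10.0), method="kmeans")


class TestInteraction:
    @pytest.mark.parametrize("q1,q2,q12,expected", [
        (0.2, 0.3, 0.1, "nonlinear weaken"),
        (0.2, 0.3, 0.25, "single-factor nonlinear weaken"),
        (0.2, 0.3, 0.4, "two-factor enhancement"),
        (0.2, 0.3, 0.5, "independent"),
        (0.2, 0.3, 0.6, "nonlinear enhancement"),
    ])
    def test_rule_table(self, q1, q2, q12, expected):
        assert classify_interaction(q1, q2, q12) == expected

    def test_idempotent_overlay_is_single_factor_class(self, rng):
        y = rng.normal(size=60)
        s = rng.integers(0, 4, size=60)
        rep = interaction_q(y, s, s)
        assert rep.q12 == pytest.approx(rep.q1, abs=1e-12)
        assert rep.interaction_type == "single-factor nonlinear weaken"

    def test_refinement_never_decreases_q(self, rng):
        """Overlay q >= max of the single-factor q values."""
        for _ in range(30):
            y = rng.normal(size=80)
            s1 = rng.integers(0, 4, size=80)
            s2 = rng.integers(0, 3, size=80)
            rep = interaction_q(y, s1, s2)
            assert rep.q12 >= max(rep.q1, rep.q2) - 1e-12

    def test_report_fields(self, rng):
        y = rng.normal(size=50)
        rep = interaction_q(y, rng.integers(0, 3, size=50),
                            rng.integers(0, 3, size=50))
        assert isinstance(rep, InteractionReport)
        assert rep.interaction_type in {
            "nonlinear weaken", "single-factor nonlinear weaken",
            "two-factor enhancement", "independent", "nonlinear enhancement"}

    def test_overlay_invalid_propagates(self):
        s = overlay_strata([0, 1, -1], [1, 1, 1])
        assert s[2] == -1
        assert s[0] != s[1]


class TestFactorReport:
    def _y(self, rng):
        return Grid(rng.normal(size=(12, 12)))

    def test_copy_of_response_ranks_first(self, rng):
        y = self._y(rng)
        factors = {
            "self": {"grid": y},
            "noise": {"grid": Grid(rng.normal(size=(12, 12)))},
        }
        q_table, inter = factor_report({2000: y}, factors, k=8)
        tbl = q_table.set_index("factor")
        assert tbl.loc["self", "q"] > 0.8
        assert tbl.loc["self", "rank"] == 1
        assert tbl.loc["noise", "q"] < tbl.loc["self", "q"]
        assert inter[2000].loc["self", "noise"] >= tbl.loc["self", "q"] - 1e-12

    def test_independent_factor_near_zero(self, rng):
        qs = []
        for _ in range(20):
            y = rng.normal(size=200)
            s = discretize(rng.normal(size=200), k=5)
            qs.append(q_statistic(y, s))
        assert np.mean(qs) < 0.05

    def test_permutation_destroys_q(self, rng):
        y = rng.normal(size=400)
        factor = y + 0.1 * rng.normal(size=400)  # informative
        s = discretize(factor, k=5)
        q_real = q_statistic(y, s)
        q_perm = q_statistic(y, rng.permutation(s))
        assert q_real > 0.8
        assert q_perm < q_real / 2

    def test_per_year_factors(self, rng):
        years = [2000, 2010]
        ys = {y: self._y(rng) for y in years}
        factors = {
            "static": {"grid": Grid(rng.normal(size=(12, 12)))},
            "dynamic": {"grid": {y: Grid(rng.normal(size=(12, 12))) for y in years}},
        }
        q_table, inter = factor_report(ys, factors, k=4)
        assert set(q_table["year"]) == set(years)
        assert len(inter) == 2
        for mat in inter.values():
            assert mat.shape == (2, 2)
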