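"""Geographical detector: discretization search, q statistic, interactions."""

import itertools

import numpy as np
import pytest

from hqscape import (classify_interaction, discretize, factor_report,
                     interaction_detect, optimize_discretization, q_statistic)
from hqscape.grid import Raster
from hqscape.opgd import FactorStack, compute_breaks


def raster_of(values) -> Raster:
    values = np.atleast_2d(np.asarray(values, float))
    return Raster(values=values, cell_size=30.0,
                  mask=np.ones(values.shape, bool))


def naive_q(response: np.ndarray, strata: np.ndarray) -> float:
    """1 - pooled within-group SS / total SS, by an explicit group loop."""
    total_ss = float(((response - response.mean()) ** 2).sum())
    within = 0.0
    for s in np.unique(strata):
        grp = response[strata == s]
        within += float(((grp - grp.mean()) ** 2).sum())
    return 1.0 - within / total_ss


class TestDiscretize:
    def test_equal_width_splits_one_to_ten_at_midpoint(self):
        disc, grid = discretize(raster_of(range(1, 11)), "equal", 2)
        assert disc.break_points == pytest.approx([5.5])
        assert (grid == 0).sum() == 5 and (grid == 1).sum() == 5

    def test_quantile_five_classes_of_two(self):
        _, grid = discretize(raster_of(range(1, 11)), "quantile", 5)
        counts = np.bincount(grid.ravel())
        np.testing.assert_array_equal(counts, [2, 2, 2, 2, 2])

    def test_natural_breaks_beats_every_other_partition(self):
        """Fisher–Jenks minimizes total within-class SS: check exhaustively
        against all contiguous 3-class partitions of a skewed sample."""
        rng = np.random.default_rng(8)
        x = np.sort(np.concatenate([rng.normal(0, 1, 20),
                                    rng.normal(8, 0.5, 15),
                                    rng.normal(20, 2, 13)]))
        disc, grid = discretize(raster_of(x), "natural_breaks", 3)
        labels = grid.ravel()

        def within_ss(lbl):
            return sum(((x[lbl == s] - x[lbl == s].mean()) ** 2).sum()
                       for s in np.unique(lbl))

        achieved = within_ss(labels)
        n = x.size
        for c1, c2 in itertools.combinations(range(1, n), 2):
            lbl = np.zeros(n, int)
            lbl[c1:c2] = 1
            lbl[c2:] = 2
            assert achieved <= within_ss(lbl) + 1e-9

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            discretize(raster_of([1, 1, 2, 2]), "quantile", 3)

    @pytest.mark.parametrize("method", ["equal", "quantile", "natural_breaks",
                                        "geometric", "standard_deviation"])
    def test_every_method_yields_valid_partition(self, method):
        rng = np.random.default_rng(9)
        r = raster_of(rng.lognormal(0, 1, 200))
        disc, grid = discretize(r, method, 4)
        assert np.all(np.diff(disc.break_points) > 0)
        labels = grid[r.mask]
        assert labels.min() == 0
        assert np.unique(labels).size >= 2
        assert np.array_equal(np.unique(labels),
                              np.arange(np.unique(labels).size))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            compute_breaks(np.arange(10.0), "headtails", 3)


class TestQStatistic:
    def test_level_set_partition_gives_q_one(self):
        resp = np.array([1.0, 1.0, 2.0, 2.0, 5.0, 5.0])
        strata = np.array([0, 0, 1, 1, 2, 2])
        assert q_statistic(resp, strata).q == pytest.approx(1.0)

    def test_worked_six_cell_example(self):
        """response (1,1,2,5,5,6) split (A,A,A|B,B,B): hand computation gives
        q = 1 - 12/228 = 0.947368..., confirmed by the group-loop oracle."""
        resp = np.array([1.0, 1.0, 2.0, 5.0, 5.0, 6.0])
        strata = np.array([0, 0, 0, 1, 1, 1])
        q = q_statistic(resp, strata).q
        assert q == pytest.approx(0.9473684210526315, abs=1e-12)
        assert q == pytest.approx(naive_q(resp, strata), abs=1e-12)

    def test_random_strata_explain_almost_nothing(self):
        qs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            resp = rng.random(10_000)
            strata = rng.integers(0, 2, 10_000)
            qs.append(q_statistic(resp, strata).q)
        assert np.mean(qs) < 0.01

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_group_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        resp = rng.random(300)
        strata = rng.integers(0, 6, 300)
        assert q_statistic(resp, strata).q == pytest.approx(
            naive_q(resp, strata), abs=1e-12)

    def test_affine_response_and_relabel_invariance(self):
        rng = np.random.default_rng(3)
        resp = rng.random(200)
        strata = rng.integers(0, 4, 200)
        q0 = q_statistic(resp, strata).q
        assert q_statistic(5.0 * resp - 2.0, strata).q == pytest.approx(q0, abs=1e-12)
        assert q_statistic(resp, 10 - strata).q == pytest.approx(q0, abs=1e-12)

    def test_refinement_never_decreases_q(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            resp = rng.random(120)
            coarse = rng.integers(0, 3, 120)
            split = rng.integers(0, 2, 120)
            fine = coarse * 2 + split
            assert (q_statistic(resp, fine).q
                    >= q_statistic(resp, coarse).q - 1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="strata"):
            q_statistic(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(ValueError, match="variance"):
            q_statistic(np.ones(4), np.array([0, 0, 1, 1]))


class TestOptimizeDiscretization:
    def test_step_function_recovered_exactly(self):
        x = np.concatenate([np.linspace(0, 1, 40), np.linspace(5, 6, 40),
                            np.linspace(10, 11, 40)])
        resp = np.repeat([0.2, 0.5, 0.9], 40)
        disc, qr = optimize_discretization(
            raster_of(resp), raster_of(x), n_classes_range=range(2, 6))
        assert qr.q == pytest.approx(1.0)
        assert qr.n_strata == 3  # smallest class count achieving q = 1 wins

    def test_degenerate_search_equals_direct_q(self):
        rng = np.random.default_rng(5)
        x = raster_of(rng.random(100))
        resp = raster_of(rng.random(100))
        disc, qr = optimize_discretization(resp, x, methods=("equal",),
                                           n_classes_range=range(2, 3))
        _, grid = discretize(x, "equal", 2)
        assert qr.q == pytest.approx(
            q_statistic(resp.masked(), grid[x.mask]).q, abs=1e-15)

    def test_empty_search_rejected(self):
        x = raster_of([1.0, 1.0, 1.0, 2.0])
        resp = raster_of([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="no valid"):
            optimize_discretization(resp, x, methods=("quantile",),
                                    n_classes_range=range(5, 6))


class TestInteraction:
    @pytest.mark.parametrize("q1,q2,q12,expect", [
        (0.3, 0.4, 0.8, "nonlinear enhancement"),       # > q1 + q2
        (0.3, 0.4, 0.5, "dual-factor enhancement"),     # > max
        (0.3, 0.4, 0.2, "nonlinear diminishing"),       # < min
        (0.3, 0.4, 0.35, "single-factor nonlinear diminishing"),
        (0.3, 0.4, 0.7, "independent"),                 # exact equality
        (0.3, 0.4, 0.7 + 5e-13, "independent"),         # within tolerance
        (0.3, 0.4, 0.70001, "nonlinear enhancement"),   # precedence over dual
    ])
    def test_taxonomy(self, q1, q2, q12, expect):
        assert classify_interaction(q1, q2, q12) == expect

    def test_self_interaction_equals_single_factor_q(self):
        rng = np.random.default_rng(7)
        resp = rng.random(400)
        strata = rng.integers(0, 5, 400)
        res = interaction_detect(resp, strata, strata)
        assert res.q12 == pytest.approx(res.q1, abs=1e-12)

    def test_product_strata_match_oracle(self):
        rng = np.random.default_rng(11)
        resp = rng.random(500)
        a = rng.integers(0, 3, 500)
        b = rng.integers(0, 4, 500)
        res = interaction_detect(resp, a, b)
        assert res.q12 == pytest.approx(naive_q(resp, a * 10 + b), abs=1e-12)
        assert res.q12 >= max(res.q1, res.q2) - 1e-12  # refinement bound

    def test_collapsed_product_rejected(self):
        resp = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="strat"):
            interaction_detect(resp, np.zeros(3, int), np.zeros(3, int))


class TestFactorReport:
    def _stack(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        mask = np.ones((n, n), bool)
        driver = Raster(values=rng.random((n, n)), cell_size=30.0, mask=mask)
        noise = Raster(values=rng.standard_normal((n, n)), cell_size=30.0,
                       mask=mask)
        resp = Raster(values=np.clip(driver.values
                                     + 0.1 * rng.standard_normal((n, n)),
                                     0, 1),
                      cell_size=30.0, mask=mask)
        return resp, FactorStack(layers={"driver": driver, "noise": noise})

    def test_planted_driver_ranked_first(self):
        resp, stack = self._stack(seed=1)
        report = factor_report(resp, stack)
        assert report.factors.loc[0, "factor"] == "driver"
        assert (report.interactions["q12"] >= 0).all()

    def test_single_factor_rejected(self):
        resp, stack = self._stack(seed=2)
        solo = FactorStack(layers={"driver": stack.layers["driver"]})
        with pytest.raises(ValueError, match="2 factors"):
            factor_report(resp, solo)

    def test_categorical_factor_used_as_is(self):
        rng = np.random.default_rng(4)
        mask = np.ones((30, 30), bool)
        cat = Raster(values=rng.integers(1, 4, (30, 30)).astype(float),
                     cell_size=30.0, mask=mask)
        cont = Raster(values=rng.random((30, 30)), cell_size=30.0, mask=mask)
        resp = Raster(values=rng.random((30, 30)), cell_size=30.0, mask=mask)
        report = factor_report(resp, FactorStack(
            layers={"intensity": cat, "cont": cont},
            categorical={"intensity"}))
        row = report.factors.set_index("factor").loc["intensity"]
        assert row["method"] == "categorical"
        assert row["n_classes"] == 3
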