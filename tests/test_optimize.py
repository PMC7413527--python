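import numpy as np
import pandas as pd
import pytest
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, Matern

from fertresponse import optimize as opt
from fertresponse.mitscherlich import MitscherlichParams


@pytest.fixture(scope="module")
def prices():
    return opt.PriceModel()


@pytest.fixture(scope="module")
def truth_fn(truth_params):
    return opt.surface_response(truth_params)


def brute_force_best(fn, points, prices=None):
    """Row-by-row loop oracle for the grid argmax (same tie-break rules)."""
    best_i, best_val = -1, -np.inf
    preds = fn(points)
    for i, (d, y) in enumerate(zip(points, preds)):
        val = y if prices is None else (
            y * prices.tuber_price - d[0] * prices.cost_N
            - d[1] * prices.cost_P - d[2] * prices.cost_K)
        better = val > best_val + 1e-9
        tie = abs(val - best_val) <= 1e-9
        if better or (tie and (d.sum(), d[0]) < (points[best_i].sum(), points[best_i][0])):
            best_i, best_val = i, max(val, best_val)
    return points[best_i], best_val


class TestNetReturn:
    def test_zero_yield_zero_dose(self, prices):
        assert opt.net_return(0.0, (0.0, 0.0, 0.0), prices) == 0.0

    def test_hand_value(self, prices):
        val = opt.net_return(30.0, (100.0, 50.0, 100.0), prices)
        assert val == pytest.approx(7500.0 - (120.0 + 55.0 + 90.0))

    def test_decreasing_in_dose_at_fixed_yield(self, prices, rng):
        d = rng.uniform(0, 200, 3)
        base = opt.net_return(20.0, d, prices)
        for j in range(3):
            d2 = d.copy()
            d2[j] += 10.0
            assert opt.net_return(20.0, d2, prices) < base

    def test_decomposition_exact(self, prices, rng):
        y = rng.uniform(0, 50, 100)
        d = rng.uniform(0, 200, (100, 3))
        ret = opt.net_return(y, d, prices)
        cost = d @ prices.costs
        np.testing.assert_allclose(ret + cost, y * prices.tuber_price, rtol=1e-14)

    def test_negative_prices_rejected(self):
        with pytest.raises(ValueError):
            opt.PriceModel(cost_N=-1.0)


class TestDoseGrid:
    def test_uniform_points_within_bounds(self):
        grid = opt.DoseGrid.uniform(500, seed=1)
        assert grid.points.shape == (500, 3)
        for j, b in enumerate(grid.bounds):
            assert np.all((grid.points[:, j] >= 0) & (grid.points[:, j] <= b))

    def test_seeded_reproducibility(self):
        g1 = opt.DoseGrid.uniform(100, seed=5)
        g2 = opt.DoseGrid.uniform(100, seed=5)
        np.testing.assert_array_equal(g1.points, g2.points)

    def test_lattice_covers_corners(self):
        lat = opt.DoseGrid.lattice(5)
        assert [250.0, 110.0, 208.0] in lat.points.tolist()
        assert [0.0, 0.0, 0.0] in lat.points.tolist()


class TestEconomicOptimum:
    def test_flat_model_picks_cheapest_grid_point(self, prices):
        grid = opt.DoseGrid.uniform(200, seed=2)
        rec = opt.economic_optimum(lambda d: np.full(len(d), 25.0), grid, prices)
        cheapest = grid.points[np.argmin(grid.points @ prices.costs)]
        np.testing.assert_allclose(rec.optimum, cheapest)

    def test_matches_brute_force_oracle(self, truth_fn, prices):
        grid = opt.DoseGrid.uniform(400, seed=3)
        rec = opt.economic_optimum(truth_fn, grid, prices)
        best_d, best_val = brute_force_best(truth_fn, grid.points, prices)
        np.testing.assert_allclose(rec.optimum, best_d)
        assert rec.net_return == pytest.approx(best_val, abs=1e-9)

    def test_zero_prices_agree_with_agronomic(self, truth_fn):
        grid = opt.DoseGrid.uniform(300, seed=4)
        zero = opt.PriceModel(0.0, 0.0, 0.0, 1.0)
        econ = opt.economic_optimum(truth_fn, grid, zero)
        agro = opt.agronomic_optimum(truth_fn, grid)
        np.testing.assert_allclose(econ.optimum, agro.optimum)

    def test_lattice_return_bounds_random_grid_and_gap_shrinks(self, truth_fn, prices):
        lat = opt.DoseGrid.lattice(50)
        best = opt.economic_optimum(truth_fn, lat, prices).net_return
        gaps = []
        for n in (100, 1000, 10000):
            rec = opt.economic_optimum(truth_fn, opt.DoseGrid.uniform(n, seed=1), prices)
            assert rec.net_return <= best + 1e-9
            gaps.append(best - rec.net_return)
        assert gaps[2] < gaps[0]

    def test_oxide_doses_reported(self, truth_fn, prices):
        rec = opt.economic_optimum(truth_fn, opt.DoseGrid.uniform(100, seed=0), prices)
        assert rec.oxide_doses[0] == pytest.approx(rec.optimum[1] * 2.291)
        assert rec.oxide_doses[1] == pytest.approx(rec.optimum[2] * 1.205)


class TestAgronomicOptimum:
    def test_monotone_response_picks_largest_sampled_dose(self):
        grid = opt.DoseGrid.uniform(500, seed=6)
        rec = opt.agronomic_optimum(lambda d: d[:, 0], grid)
        assert rec.optimum[0] == grid.points[:, 0].max()

    def test_matches_brute_force_oracle(self, truth_fn):
        grid = opt.DoseGrid.uniform(400, seed=7)
        rec = opt.agronomic_optimum(truth_fn, grid)
        best_d, _ = brute_force_best(truth_fn, grid.points)
        np.testing.assert_allclose(rec.optimum, best_d)

    def test_agronomic_n_dose_at_least_economic(self, truth_fn, prices):
        lat = opt.DoseGrid.lattice(40)
        agro = opt.agronomic_optimum(truth_fn, lat)
        econ = opt.economic_optimum(truth_fn, lat, prices)
        assert agro.optimum[0] >= econ.optimum[0] - 1e-9


class TestResponseCurve:
    def test_constant_model_flat(self):
        doses, preds = opt.response_curve(lambda d: np.full(len(d), 7.0),
                                          (10.0, 10.0, 10.0), "N")
        assert np.ptp(preds) == 0.0

    def test_matches_closed_form(self, truth_fn, truth_params):
        fixed = (0.0, 50.0, 120.0)
        doses, preds = opt.response_curve(truth_fn, fixed, "N", (0.0, 260.0), 50)
        A = truth_params.value("A")
        expected = (A * (1 - np.exp(-0.012 * (40.0 + doses)))
                    * (1 - np.exp(-0.025 * (25.0 + 50.0)))
                    * (1 - np.exp(-0.008 * (60.0 + 120.0))))
        np.testing.assert_allclose(preds, expected, atol=1e-9)

    def test_endpoints_respect_range(self, truth_fn):
        doses, _ = opt.response_curve(truth_fn, (0, 0, 0), "K", (5.0, 199.0), 10)
        assert doses[0] == 5.0 and doses[-1] == 199.0

    def test_unknown_nutrient_rejected(self, truth_fn):
        with pytest.raises(ValueError):
            opt.response_curve(truth_fn, (0, 0, 0), "Mg")


class TestRestandardization:
    def test_dose_overwrite_equals_fresh_standardization(self, rng):
        from fertresponse.preprocess import Standardizer

        raw = pd.DataFrame({
            "dose_N": rng.uniform(0, 260, 60), "dose_P": rng.uniform(0, 130, 60),
            "dose_K": rng.uniform(0, 350, 60), "ph_water": rng.uniform(5, 7, 60),
        })
        std = Standardizer().fit(raw)
        row = raw.iloc[0]
        new_doses = rng.uniform(0, 100, (20, 3))
        via_overwrite = opt.dose_feature_matrix(row, new_doses, std)
        fresh = pd.DataFrame([row.to_dict()] * 20)
        fresh[["dose_N", "dose_P", "dose_K"]] = new_doses
        np.testing.assert_allclose(via_overwrite.to_numpy(),
                                   std.transform(fresh).to_numpy(), atol=1e-9)


@pytest.fixture(scope="module")
def dose_gp(truth_params):
    """GP fitted on near-noiseless Mitscherlich yields over random doses."""
    rng = np.random.default_rng(10)
    doses = rng.uniform(0, 1, (150, 3)) * np.array([250.0, 110.0, 208.0])
    fn = opt.surface_response(truth_params)
    y = fn(doses) + rng.normal(0, 0.2, 150)
    gp = GaussianProcessRegressor(
        kernel=RBF(length_scale=0.5, length_scale_bounds="fixed"),
        alpha=0.04, normalize_y=True, random_state=0)
    return gp.fit(doses / np.array([250.0, 110.0, 208.0]), y)


class TestSampleOptimalDoses:
    @staticmethod
    def _fixed_row():
        return pd.Series({"dose_N": 0.0, "dose_P": 0.0, "dose_K": 0.0})

    @staticmethod
    def _scaled_predictor(gp):
        class Scaled:
            X_train_ = gp.X_train_

            def predict(self, X, return_cov=False):
                return gp.predict(X / np.array([250.0, 110.0, 208.0]),
                                  return_cov=return_cov)
        return Scaled()

    def test_degenerate_posterior_collapses_to_mean_optimum(self, truth_params):
        rng = np.random.default_rng(4)
        doses = rng.uniform(0, 1, (80, 3)) * np.array([250.0, 110.0, 208.0])
        fn = opt.surface_response(truth_params)
        gp = GaussianProcessRegressor(kernel=RBF(length_scale=1.0), alpha=1e-10,
                                      normalize_y=True, random_state=0)
        gp.fit(doses / np.array([250.0, 110.0, 208.0]), fn(doses))
        scaled = self._scaled_predictor(gp)
        grid = opt.DoseGrid(points=doses, bounds=(250.0, 110.0, 208.0))
        rec = opt.sample_optimal_doses(scaled, self._fixed_row(), grid,
                                       n_samples=200, mode="agronomic", seed=0)
        assert np.ptp(rec.per_sample_optima, axis=0).max() < 1e-6
        np.testing.assert_allclose(rec.per_sample_optima[0], rec.mean_curve_optimum,
                                   atol=1e-9)

    def test_percentiles_non_decreasing(self, dose_gp):
        grid = opt.DoseGrid.uniform(300, seed=8)
        rec = opt.sample_optimal_doses(self._scaled_predictor(dose_gp),
                                       self._fixed_row(), grid,
                                       n_samples=300, mode="economic", seed=1)
        for nut in ("N", "P", "K"):
            vals = [rec.percentiles[nut][p] for p in sorted(rec.percentiles[nut])]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_modal_bin_stable_across_seeds(self, dose_gp):
        grid = opt.DoseGrid.uniform(300, seed=9)
        recs = [opt.sample_optimal_doses(self._scaled_predictor(dose_gp),
                                         self._fixed_row(), grid,
                                         n_samples=1000, mode="economic", seed=s)
                for s in (1, 2)]
        for j, nut in enumerate(("N", "P", "K")):
            width = grid.bounds[j] / opt.MODAL_BINS
            assert abs(recs[0].modal_dose[nut] - recs[1].modal_dose[nut]) <= width + 1e-9

    def test_monotone_posterior_pushes_optima_to_edges(self):
        # GP trained on a linear upward trend in N -> sampled agronomic optima
        # accumulate at the upper grid edge
        rng = np.random.default_rng(2)
        doses = rng.uniform(0, 1, (60, 3)) * np.array([250.0, 110.0, 208.0])
        y = 0.1 * doses[:, 0]
        gp = GaussianProcessRegressor(kernel=RBF(length_scale=2.0), alpha=1e-6,
                                      normalize_y=True, random_state=0)
        gp.fit(doses / np.array([250.0, 110.0, 208.0]), y)
        grid = opt.DoseGrid.uniform(200, seed=3)
        rec = opt.sample_optimal_doses(self._scaled_predictor(gp), self._fixed_row(),
                                       grid, n_samples=300, mode="agronomic", seed=0)
        top_decile = 0.9 * 250.0
        assert (rec.per_sample_optima[:, 0] >= top_decile).mean() > 0.5

    def test_too_few_samples_rejected(self, dose_gp):
        grid = opt.DoseGrid.uniform(50, seed=0)
        with pytest.raises(ValueError, match="n_samples"):
            opt.sample_optimal_doses(self._scaled_predictor(dose_gp),
                                     self._fixed_row(), grid, n_samples=1)


class TestConditionalExpectationDose:
    def test_constant_optima_return_that_dose(self):
        assert opt.conditional_expectation_dose(np.full(50, 120.0), 80.0) == 120.0

    def test_order_statistic_example(self):
        optima = [0.0, 100.0, 200.0, 300.0, 400.0]
        assert opt.conditional_expectation_dose(optima, 50.0) == 200.0

    def test_monotone_in_percentile(self, rng):
        optima = rng.uniform(0, 250, 500)
        xs = np.linspace(1, 100, 60)
        vals = [opt.conditional_expectation_dose(optima, x) for x in xs]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            opt.conditional_expectation_dose([], 50.0)

    @pytest.mark.parametrize("x", [0.0, -5.0, 101.0])
    def test_bad_percentile_rejected(self, x):
        with pytest.raises(ValueError):
            opt.conditional_expectation_dose([1.0, 2.0], x)
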