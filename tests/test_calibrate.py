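import numpy as np
import pytest

from emrestore.benchmarks import calibration_apply_fn, make_benchmark
from emrestore.calibrate import (
    CalibrationTable,
    build_table,
    fit_polynomial,
    grid_points,
    grid_search_optimal,
    predict_params,
    select_degree,
)
from emrestore.core import DegradationModel, ImageVolume, degrade


class TestGridSearch:
    def test_single_point_grid_returned(self):
        bench = [np.full((16, 16), 0.5)]
        out = grid_search_optimal(
            calibration_apply_fn("gaussian"), bench, 0.1, {"sigma_g": [1.0]}, seed=0
        )
        assert out == {"sigma_g": 1.0}

    def test_matches_exhaustive_oracle(self, rng):
        bench = [rng.random((32, 32)), rng.random((32, 32))]
        grid = {"sigma_g": [0.5, 1.0, 2.0]}
        apply_fn = calibration_apply_fn("gaussian")
        found = grid_search_optimal(apply_fn, bench, 0.1, grid, seed=3)
        # independent exhaustive re-evaluation with identical seeding
        sses = {}
        for sg in grid["sigma_g"]:
            sse = 0.0
            for k, x in enumerate(bench):
                vol = ImageVolume(x)
                ym = degrade(vol, DegradationModel(0.0, 0.1, seed=3 * 10_007 + k))
                sse += float(((apply_fn(ym.data[0], {"sigma_g": sg}) - vol.data[0]) ** 2).sum())
            sses[sg] = sse
        assert found["sigma_g"] == min(sses, key=sses.get)

    def test_constant_truth_prefers_strongest_smoothing(self):
        bench = [np.full((32, 32), 0.5)]
        grid = {"sigma_g": [0.5, 1.0, 2.0, 3.0]}
        out = grid_search_optimal(calibration_apply_fn("gaussian"), bench, 0.1, grid, seed=1)
        assert out == {"sigma_g": 3.0}

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            grid_search_optimal(calibration_apply_fn("gaussian"), [], 0.1, {"sigma_g": [1.0]})
        with pytest.raises(ValueError):
            grid_search_optimal(
                calibration_apply_fn("gaussian"), [np.zeros((8, 8))], 0.1, {"sigma_g": []}
            )

    def test_cartesian_grid_order(self):
        pts = grid_points({"a": [1, 2], "b": [10, 20]})
        assert pts[0] == {"a": 1, "b": 10} and pts[-1] == {"a": 2, "b": 20}


class TestPolynomialFit:
    def test_exact_linear_law(self):
        sig = [0.05, 0.1, 0.2]
        theta = [[2 * s] for s in sig]
        coeffs = fit_polynomial(sig, theta, 1)
        np.testing.assert_allclose(coeffs, [[0.0, 2.0]], atol=1e-10)

    def test_exact_quadratic_law(self):
        sig = [0.05, 0.1, 0.15, 0.2]
        theta = [[s**2] for s in sig]
        coeffs = fit_polynomial(sig, theta, 2)
        np.testing.assert_allclose(coeffs, [[0.0, 0.0, 1.0]], atol=1e-10)

    def test_quadratic_residual_never_worse(self, rng):
        sig = [0.02, 0.05, 0.1, 0.15, 0.2]
        theta = [[v] for v in rng.random(5)]
        from emrestore.calibrate import _fit_residual

        assert _fit_residual(sig, theta, 2) <= _fit_residual(sig, theta, 1) + 1e-12

    def test_conflicting_repeated_levels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_polynomial([0.1, 0.1], [[1.0], [2.0]], 1)

    def test_degree_selection_prefers_linear(self):
        sig = [0.05, 0.1, 0.2]
        theta = [[0.5 + 3 * s] for s in sig]
        assert select_degree(sig, theta) == 1


class TestPredict:
    def _table(self, coeffs, bounds=None):
        return CalibrationTable(
            algorithm="gaussian",
            param_names=["sigma_g"],
            sigma_grid=[0.05, 0.1, 0.2],
            theta_grid=[[0.0], [0.0], [0.0]],
            coeffs=[coeffs],
            degree=len(coeffs) - 1,
            K=1,
            param_bounds=bounds or {},
        )

    def test_linear_evaluation(self):
        assert predict_params(0.1, self._table([0.0, 2.0]))["sigma_g"] == pytest.approx(0.2)

    def test_zero_sigma_gives_intercept(self):
        assert predict_params(0.0, self._table([0.7, 2.0]))["sigma_g"] == pytest.approx(0.7)

    def test_clipped_to_bounds(self):
        t = self._table([0.0, 100.0], bounds={"sigma_g": [0.5, 3.0]})
        assert predict_params(0.2, t)["sigma_g"] == 3.0

    def test_extrapolation_warns(self):
        with pytest.warns(RuntimeWarning, match="extrapolating"):
            predict_params(1.0, self._table([0.0, 2.0]))

    def test_end_to_end_linear_law_recovery(self):
        # theta_m = 0.5 + 3*sigma_m  =>  theta_hat(0.15) = 0.95
        sig = [0.02, 0.05, 0.1, 0.2]
        theta = [[0.5 + 3 * s] for s in sig]
        coeffs = fit_polynomial(sig, theta, 1)
        table = CalibrationTable(
            algorithm="gaussian",
            param_names=["sigma_g"],
            sigma_grid=sig,
            theta_grid=theta,
            coeffs=[[float(c) for c in coeffs[0]]],
            degree=1,
            K=4,
        )
        assert predict_params(0.15, table)["sigma_g"] == pytest.approx(0.95, abs=1e-9)

    def test_table_json_roundtrip(self):
        t = self._table([0.1, 2.0], bounds={"sigma_g": [0.5, 3.0]})
        assert CalibrationTable.from_json(t.to_json()) == t


class TestBuildTable:
    def test_deterministic_and_monotone_for_gaussian(self):
        bench = make_benchmark(K=3, size=64, seed=1)
        t1 = build_table(
            "gaussian", calibration_apply_fn("gaussian"), bench, [0.05, 0.1, 0.2], seed=2
        )
        t2 = build_table(
            "gaussian", calibration_apply_fn("gaussian"), bench, [0.05, 0.1, 0.2], seed=2
        )
        assert t1.to_json() == t2.to_json()
        # more noise should never call for less smoothing
        thetas = [t[0] for t in t1.theta_grid]
        assert thetas == sorted(thetas)
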