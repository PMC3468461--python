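import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonoseed.design import decode
from sonoseed.response_surface import (
    PAIRS,
    QuadraticFit,
    collect_peaks,
    default_bounds,
    fit_all_pairs,
    fit_quadratic_pair,
    stationary_point,
    surface_grid,
)


def normal_equations_oracle(xi, xj, y):
    """Independent least-squares oracle via the explicit 6x6 normal equations."""
    X = np.column_stack([np.ones_like(xi), xi, xj, xi**2, xj**2, xi * xj])
    return np.linalg.solve(X.T @ X, X.T @ y)


def quad_surface(t, c, beta):
    return (
        beta[0] + beta[1] * t + beta[2] * c + beta[3] * t**2 + beta[4] * c**2 + beta[5] * t * c
    )


class TestFitQuadraticPair:
    def test_exact_recovery_of_generating_quadratic(self, design):
        beta = np.array([50.0, 2.0, -0.5, -0.05, 0.004, 0.01])
        cond = decode(design).set_index("treatment")
        y = quad_surface(
            cond["time_min"].to_numpy(), cond["temperature_c"].to_numpy(), beta
        )
        fit = fit_quadratic_pair(y, design, "GP", ("A", "B"))
        np.testing.assert_allclose(fit.beta, beta, atol=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("pair", PAIRS)
    @pytest.mark.parametrize("response", ["GP", "PL", "RL"])
    def test_matches_normal_equations_oracle(self, design, fixture_means, pair, response):
        fit = fit_quadratic_pair(fixture_means, design, response, pair)
        cond = decode(design).set_index("treatment")
        names = {"A": "time_min", "B": "temperature_c", "C": "power_w"}
        xi = cond[names[pair[0]]].to_numpy()
        xj = cond[names[pair[1]]].to_numpy()
        y = fixture_means[f"{response.lower()}_mean"].to_numpy()
        np.testing.assert_allclose(fit.beta, normal_equations_oracle(xi, xj, y), rtol=1e-8)

    def test_published_peak_loose_check(self, design, fixture_means):
        # the temperature coordinate of the GP time/temperature surface peak
        # is reported as 40.6; the fixture fit must land within +/- 2
        fit = fit_quadratic_pair(fixture_means, design, "GP", ("A", "B"))
        sp = stationary_point(fit)
        assert sp.kind == "maximum"
        assert sp.coords[1] == pytest.approx(40.6, abs=2.0)

    def test_residual_orthogonality(self, design, fixture_means):
        fit = fit_quadratic_pair(fixture_means, design, "GP", ("A", "B"))
        cond = decode(design).set_index("treatment")
        xi = cond["time_min"].to_numpy()
        xj = cond["temperature_c"].to_numpy()
        X = np.column_stack([np.ones_like(xi), xi, xj, xi**2, xj**2, xi * xj])
        resid = fixture_means["gp_mean"].to_numpy() - fit.predict(xi, xj)
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-7)

    def test_r2_invariant_under_predictor_rescaling(self, design, fixture_means):
        from sonoseed.design import Factor

        fit = fit_quadratic_pair(fixture_means, design, "GP", ("A", "B"))
        rescaled = [
            Factor("A", "s", (300.0, 900.0, 1500.0, 2100.0)),  # minutes -> seconds
            Factor("B", "°C", (25.0, 35.0, 45.0, 55.0)),
            Factor("C", "W", (200.0, 300.0, 400.0, 500.0)),
            Factor("D", "", None),
        ]
        fit2 = fit_quadratic_pair(fixture_means, design, "GP", ("A", "B"), factors=rescaled)
        assert fit2.r2 == pytest.approx(fit.r2, rel=1e-9)

    def test_rank_deficient_pair_rejected(self, design, fixture_means):
        from sonoseed.design import Factor

        # collapse factor A's spread so its quadratic column is degenerate
        broken = [
            Factor("A", "min", (1.0, 1.0 + 1e-13, 1.0 + 2e-13, 1.0 + 3e-13)),
            Factor("B", "°C", (25.0, 35.0, 45.0, 55.0)),
            Factor("C", "W", (200.0, 300.0, 400.0, 500.0)),
            Factor("D", "", None),
        ]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_quadratic_pair(fixture_means, design, "GP", ("A", "B"), factors=broken)

    def test_raw_dataset_basis(self, design, dish_data):
        fit = fit_quadratic_pair(dish_data, design, "GP", ("A", "B"))
        assert fit.basis == "raw"
        assert fit.n == 256


class TestStationaryPoint:
    def test_analytic_vertex(self):
        # Y = -(Xi-2)^2 - (Xj-3)^2
        beta = np.array([-13.0, 4.0, 6.0, -1.0, -1.0, 0.0])
        fit = QuadraticFit("GP", ("A", "B"), beta, 1.0, 16, "treatment-means")
        sp = stationary_point(fit, bounds={"A": (0, 10), "B": (0, 10)})
        assert sp.kind == "maximum"
        assert sp.coords == pytest.approx((2.0, 3.0))
        assert np.linalg.norm(fit.gradient(*sp.coords)) == pytest.approx(0.0, abs=1e-12)

    def test_saddle_classified(self):
        beta = np.array([0.0, 0.0, 0.0, 1.0, -1.0, 0.0])  # Xi^2 - Xj^2
        fit = QuadraticFit("GP", ("A", "B"), beta, 1.0, 16, "treatment-means")
        sp = stationary_point(fit, bounds={"A": (-5, 5), "B": (-5, 5)})
        assert sp.kind == "saddle"

    def test_degenerate_hessian_flagged(self):
        beta = np.array([0.0, 1.0, 1.0, 0.0, 0.0, 0.0])  # plane
        fit = QuadraticFit("GP", ("A", "B"), beta, 1.0, 16, "treatment-means")
        sp = stationary_point(fit, bounds={"A": (0, 1), "B": (0, 1)})
        assert sp.kind == "degenerate"
        assert sp.coords is None

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # concave surfaces with the peak inside the box
        bii, bjj = -rng.uniform(0.5, 2.0), -rng.uniform(0.5, 2.0)
        bij = rng.uniform(-0.5, 0.5)
        xi0, xj0 = rng.uniform(2, 8, 2)
        bi = -2 * bii * xi0 - bij * xj0
        bj = -2 * bjj * xj0 - bij * xi0
        beta = np.array([rng.normal(), bi, bj, bii, bjj, bij])
        fit = QuadraticFit("GP", ("A", "B"), beta, 1.0, 16, "treatment-means")
        bounds = {"A": (0.0, 10.0), "B": (0.0, 10.0)}
        sp = stationary_point(fit, bounds)
        step = 0.01 * 10
        grid = np.arange(0, 10 + step / 2, step)
        gi, gj = np.meshgrid(grid, grid, indexing="ij")
        vals = fit.predict(gi, gj)
        k = np.unravel_index(np.argmax(vals), vals.shape)
        assert sp.kind == "maximum"
        assert abs(sp.coords[0] - grid[k[0]]) <= step
        assert abs(sp.coords[1] - grid[k[1]]) <= step


class TestCollectPeaks:
    def test_six_values_per_factor_from_fixture(self, design, fixture_means):
        peaks = collect_peaks(fit_all_pairs(fixture_means, design))
        for factor in ("A", "B", "C"):
            assert len(peaks.values(factor)) == 6
        assert peaks.excluded == []

    def test_published_temperature_peaks_reproduced(self, design, fixture_means):
        peaks = collect_peaks(fit_all_pairs(fixture_means, design))
        got = sorted(round(v, 1) for v in peaks.values("B"))
        assert got == sorted([40.6, 40.7, 37.3, 37.8, 39.0, 39.1])

    def test_published_power_peaks_reproduced(self, design, fixture_means):
        peaks = collect_peaks(fit_all_pairs(fixture_means, design))
        got = sorted(round(v, 1) for v in peaks.values("C"))
        assert got == sorted([304.2, 303.6, 347.4, 350.9, 348.0, 348.4])

    def test_published_time_peaks_reproduced(self, design, fixture_means):
        peaks = collect_peaks(fit_all_pairs(fixture_means, design))
        got = sorted(round(v, 1) for v in peaks.values("A"))
        assert got == sorted([23.2, 23.1, 21.8, 21.2, 21.1, 21.0])

    def test_saddle_excluded_with_warning(self, design, fixture_means):
        fits = fit_all_pairs(fixture_means, design)
        saddle = QuadraticFit(
            "GP", ("A", "B"), np.array([0.0, 0.0, 0.0, 1.0, -1.0, 0.0]), 1.0, 16, "treatment-means"
        )
        peaks = collect_peaks([saddle] + fits[1:])
        assert len(peaks.values("A")) < 6
        assert any("saddle" in msg for msg in peaks.excluded)

    def test_identical_surfaces_give_identical_values(self, design):
        cond = decode(design).set_index("treatment")
        beta = np.array([10.0, 1.0, 1.0, -0.025, -0.025, 0.0])
        y = quad_surface(cond["time_min"].to_numpy(), cond["temperature_c"].to_numpy(), beta)
        fits = [fit_quadratic_pair(y, design, r, ("A", "B")) for r in ("GP", "PL", "RL")]
        peaks = collect_peaks(fits, bounds={"A": (0, 40), "B": (0, 40)})
        np.testing.assert_allclose(peaks.values("A"), peaks.values("A")[0])
        assert len(peaks.values("A")) == 3


class TestSurfaceGrid:
    def test_corner_predictions(self, design, fixture_means):
        fit = fit_quadratic_pair(fixture_means, design, "GP", ("A", "B"))
        grid = surface_grid(fit, resolution=2)
        assert len(grid) == 4
        for row in grid.itertuples():
            assert row.yhat == pytest.approx(float(fit.predict(row.xi, row.xj)))

    def test_grid_max_consistent_with_stationary_point(self, design, fixture_means):
        fit = fit_quadratic_pair(fixture_means, design, "GP", ("A", "B"))
        sp = stationary_point(fit)
        grid = surface_grid(fit, resolution=101)
        top = grid.loc[grid["yhat"].idxmax()]
        bounds = default_bounds()
        step_i = (bounds["A"][1] - bounds["A"][0]) / 100
        step_j = (bounds["B"][1] - bounds["B"][0]) / 100
        assert abs(top["xi"] - sp.coords[0]) <= step_i
        assert abs(top["xj"] - sp.coords[1]) <= step_j

    def test_constant_surface(self):
        beta = np.array([7.0, 0, 0, 0, 0, 0.0])
        fit = QuadraticFit("GP", ("A", "B"), beta, 0.0, 16, "treatment-means")
        grid = surface_grid(fit, bounds={"A": (0, 1), "B": (0, 1)}, resolution=5)
        np.testing.assert_allclose(grid["yhat"], 7.0)
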