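import time

import numpy as np
import pytest

from brainsgm import (
    NoiseModel,
    RegionalPSD,
    SGMParameters,
    band_power,
    default_grid,
    eqn1_transfer,
    forward_psd,
    from_db,
    to_db,
)
from brainsgm.forward_model import SpectralCache
from brainsgm.local_model import gamma_response, local_transfer
from conftest import random_graph


def scalar_decoupled_psd(params: SGMParameters, grid: np.ndarray) -> np.ndarray:
    """Closed form for alpha=0: every region is the same scalar filter."""
    omega = 2 * np.pi * grid
    FG = gamma_response(grid, params.tau_G)
    H = local_transfer(grid, params)
    return np.abs(FG * H / (1j * omega + FG / params.tau_G)) ** 2


class TestEqn1Transfer:
    def test_alpha_zero_is_scalar_identity(self, small_graph, grid):
        p = SGMParameters(alpha=0.0)
        f = 10.0
        T = eqn1_transfer(small_graph, p, f).transfer
        omega = 2 * np.pi * f
        FG = complex(gamma_response(f, p.tau_G))
        H = complex(local_transfer(f, p))
        scalar = FG * H / (1j * omega + FG / p.tau_G)
        assert np.allclose(T, scalar * np.eye(small_graph.n_regions), atol=1e-10)

    def test_two_node_closed_form(self, two_node_graph):
        # lambda = 1 -/+ alpha e^{-i theta}; T is the resolvent-weighted sum of
        # the symmetric/antisymmetric projectors
        p = SGMParameters(alpha=0.5, speed_v=1.0)
        f = 0.25
        theta = 2 * np.pi * f * 1.0 / 1.0
        omega = 2 * np.pi * f
        FG = complex(gamma_response(f, p.tau_G))
        H = complex(local_transfer(f, p))
        lam = np.array([1 - p.alpha * np.exp(-1j * theta), 1 + p.alpha * np.exp(-1j * theta)])
        P_sym = np.full((2, 2), 0.5)
        P_anti = np.array([[0.5, -0.5], [-0.5, 0.5]])
        weights = 1.0 / (1j * omega + lam * FG / p.tau_G)
        expected = (weights[0] * P_sym + weights[1] * P_anti) * FG * H
        T = eqn1_transfer(two_node_graph, p, f).transfer
        assert np.allclose(T, expected, atol=1e-10)

    @pytest.mark.parametrize("n", [5, 10, 20])
    def test_eigen_sum_equals_direct_solve_zero_delay(self, n, grid):
        g = random_graph(n, seed=n, zero_delay=True)
        p = SGMParameters()
        for f in grid[::10]:
            Ts = eqn1_transfer(g, p, float(f), "eigen_sum").transfer
            Td = eqn1_transfer(g, p, float(f), "direct_solve").transfer
            assert np.max(np.abs(Ts - Td)) < 1e-8 * np.max(np.abs(Td))

    def test_unknown_method_rejected(self, small_graph):
        with pytest.raises(ValueError):
            eqn1_transfer(small_graph, SGMParameters(), 10.0, method="magic")


class TestForwardPSD:
    def test_alpha_zero_regions_identical_and_match_scalar(self, small_graph, grid):
        p = SGMParameters(alpha=0.0)
        psd = forward_psd(small_graph, p, grid)
        expected = scalar_decoupled_psd(p, grid)
        for j in range(small_graph.n_regions):
            assert np.allclose(psd.values[j], expected, rtol=1e-10)
        assert np.max(psd.values.max(axis=0) - psd.values.min(axis=0)) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_positive_everywhere(self, small_graph, grid):
        psd = forward_psd(small_graph, SGMParameters(), grid)
        assert np.all(psd.values >= 0)

    def test_noise_amplitude_quadratic(self, small_graph, grid):
        p = SGMParameters()
        s1 = forward_psd(small_graph, p, grid, noise=NoiseModel(amplitude=1.0)).values
        s2 = forward_psd(small_graph, p, grid, noise=NoiseModel(amplitude=2.0)).values
        assert np.allclose(s2, 4.0 * s1, rtol=1e-12)

    def test_common_noise_mode_differs(self, small_graph, grid):
        p = SGMParameters()
        ind = forward_psd(small_graph, p, grid).values
        common = forward_psd(
            small_graph, p, grid, noise=NoiseModel(mode="common")
        ).values
        assert not np.allclose(ind, common)

    def test_cached_and_uncached_paths_identical(self, small_graph, grid):
        p = SGMParameters()
        cache = SpectralCache(small_graph, grid, p.speed_v, "symmetric_degree")
        a = forward_psd(small_graph, p, grid, cache=cache).values
        b = forward_psd(small_graph, p, grid).values
        assert np.array_equal(a, b)

    def test_eigen_sum_vs_direct_pipeline_zero_delay(self, grid):
        g = random_graph(10, seed=7, zero_delay=True)
        p = SGMParameters()
        a = forward_psd(g, p, grid, method="eigen_sum").values
        b = forward_psd(g, p, grid, method="direct_solve").values
        assert np.max(np.abs(a - b) / np.abs(b)) < 1e-8

    def test_default_grid_68_regions_under_five_seconds(self):
        from brainsgm import SyntheticSpec, generate_connectome

        g = generate_connectome(SyntheticSpec(geometry_seed=5))
        t0 = time.time()
        psd = forward_psd(g, SGMParameters())
        assert time.time() - t0 < 5.0
        assert psd.values.shape == (68, 87)


class TestDbConversion:
    @pytest.mark.parametrize("raw, db", [(1.0, 0.0), (100.0, 20.0), (0.0, -300.0)])
    def test_known_values(self, raw, db):
        psd = RegionalPSD(["A"], [1.0], np.array([[raw]]), "raw_power")
        assert to_db(psd).values[0, 0] == pytest.approx(db, abs=1e-12)

    def test_round_trip_above_floor(self, small_graph, grid):
        psd = forward_psd(small_graph, SGMParameters(), grid)
        back = from_db(to_db(psd))
        assert np.allclose(back.values, psd.values, rtol=1e-12)

    def test_db_input_rejected_by_to_db(self, small_graph, grid):
        db = to_db(forward_psd(small_graph, SGMParameters(), grid))
        with pytest.raises(ValueError):
            to_db(db)


class TestBandPower:
    def test_flat_spectrum_integrates_to_band_width(self):
        f = np.arange(2.0, 45.5, 0.5)
        psd = RegionalPSD(["A", "B"], f, np.ones((2, f.size)), "raw_power")
        prof = band_power(psd, (8.0, 12.0))
        assert np.allclose(prof.values, 4.0, atol=1e-12)

    def test_linear_spectrum_trapezoid(self):
        f = np.array([8.0, 10.0, 12.0])
        psd = RegionalPSD(["A"], f, f[None, :], "raw_power")
        assert band_power(psd, (8.0, 12.0)).values[0] == pytest.approx(40.0)

    def test_band_outside_grid_rejected(self):
        f = np.arange(2.0, 45.5, 0.5)
        psd = RegionalPSD(["A"], f, np.ones((1, f.size)), "raw_power")
        with pytest.raises(ValueError, match="outside grid"):
            band_power(psd, (50.0, 60.0))

    def test_db_input_rejected(self, small_graph, grid):
        db = to_db(forward_psd(small_graph, SGMParameters(), grid))
        with pytest.raises(ValueError, match="raw power"):
            band_power(db, (8.0, 12.0))
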