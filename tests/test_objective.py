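import numpy as np
import pytest

from brainsgm import (
    ObjectiveConfig,
    RegionalPSD,
    SGMParameters,
    SpatialProfile,
    combined_objective,
    fisher_z,
    forward_psd,
    spatial_correlation,
    spectral_correlation,
    to_db,
)
from brainsgm.connectome_io import row_degree_normalize
from brainsgm.forward_model import band_power


def _db_pair(small_graph, grid):
    psd = forward_psd(small_graph, SGMParameters(), grid)
    return to_db(psd), band_power(psd, (8.0, 12.0))


class TestSpectralCorrelation:
    def test_self_correlation_is_one(self, small_graph, grid):
        db, _ = _db_pair(small_graph, grid)
        mean_r, per_region = spectral_correlation(db, db)
        assert mean_r == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(per_region, 1.0, atol=1e-12)

    def test_per_region_affine_invariance(self, small_graph, grid):
        db, _ = _db_pair(small_graph, grid)
        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 3.0, size=(db.values.shape[0], 1))
        b = rng.uniform(-5.0, 5.0, size=(db.values.shape[0], 1))
        scaled = RegionalPSD(db.region_labels, db.frequencies_hz, a * db.values + b, "dB")
        mean_r, _ = spectral_correlation(db, scaled)
        assert mean_r == pytest.approx(1.0, abs=1e-10)

    def test_three_bin_hand_value(self):
        model = RegionalPSD(["A"], [1.0, 2.0, 3.0], np.array([[0.0, 1.0, 2.0]]), "dB")
        target = RegionalPSD(["A"], [1.0, 2.0, 3.0], np.array([[1.0, 3.0, 4.0]]), "dB")
        mean_r, _ = spectral_correlation(model, target)
        assert mean_r == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_region_excluded_with_warning(self, caplog):
        import logging

        f = [1.0, 2.0, 3.0]
        model = RegionalPSD(["A", "B"], f, np.array([[0.0, 1.0, 2.0], [5.0, 5.0, 5.0]]), "dB")
        target = RegionalPSD(["A", "B"], f, np.array([[0.0, 2.0, 4.0], [1.0, 2.0, 3.0]]), "dB")
        with caplog.at_level(logging.WARNING):
            mean_r, per_region = spectral_correlation(model, target)
        assert mean_r == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(per_region[1])
        assert any("zero-variance" in rec.message for rec in caplog.records)

    def test_per_region_r_bounded(self, small_graph, grid):
        db, _ = _db_pair(small_graph, grid)
        rng = np.random.default_rng(0)
        noisy = RegionalPSD(
            db.region_labels, db.frequencies_hz,
            db.values + rng.normal(0, 5, db.values.shape), "dB",
        )
        _, per_region = spectral_correlation(db, noisy)
        assert np.all(np.abs(per_region) <= 1.0)

    def test_mismatched_grids_rejected(self, small_graph, grid):
        db, _ = _db_pair(small_graph, grid)
        other = RegionalPSD(db.region_labels, db.frequencies_hz + 1.0, db.values, "dB")
        with pytest.raises(ValueError, match="grid"):
            spectral_correlation(db, other)


class TestSpatialCorrelation:
    def test_large_w_limit_is_pearson(self, small_graph):
        rng = np.random.default_rng(4)
        n = small_graph.n_regions
        x = SpatialProfile(small_graph.region_labels, rng.uniform(0.1, 2.0, n))
        y = SpatialProfile(small_graph.region_labels, rng.uniform(0.1, 2.0, n))
        Cn = row_degree_normalize(small_graph.C)
        s = spatial_correlation(x, y, Cn, w=1e6)
        pearson = np.corrcoef(x.values, y.values)[0, 1]
        assert abs(s - pearson) < 1e-5

    def test_two_region_identical_profiles(self):
        # x = y -> x~ = (1,-1)/sqrt2, M = [[w,1],[1,w]]/(w+1) -> s = (w-1)/(w+1)
        labels = ["A", "B"]
        x = SpatialProfile(labels, np.array([2.0, 1.0]))
        Cn = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = spatial_correlation(x, x, Cn, w=10.0)
        assert s == pytest.approx(9.0 / 11.0, abs=1e-12)

    def test_orthogonal_profiles_near_zero_at_large_w(self):
        labels = [f"R{i}" for i in range(4)]
        x = SpatialProfile(labels, np.array([1.0, 0.0, 1.0, 0.0]))
        y = SpatialProfile(labels, np.array([1.0, 1.0, 0.0, 0.0]))
        Cn = row_degree_normalize(np.ones((4, 4)) - np.eye(4))
        assert abs(spatial_correlation(x, y, Cn, w=1e8)) < 1e-6

    def test_constant_profile_rejected(self):
        labels = ["A", "B"]
        x = SpatialProfile(labels, np.array([1.0, 1.0]))
        Cn = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="constant"):
            spatial_correlation(x, x, Cn, w=10.0)

    def test_continuous_in_w_and_converges(self, small_graph):
        rng = np.random.default_rng(11)
        n = small_graph.n_regions
        x = SpatialProfile(small_graph.region_labels, rng.uniform(0.1, 2.0, n))
        y = SpatialProfile(small_graph.region_labels, rng.uniform(0.1, 2.0, n))
        Cn = row_degree_normalize(small_graph.C)
        ws = np.array([0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1e4, 1e6])
        vals = [spatial_correlation(x, y, Cn, w=w) for w in ws]
        diffs = np.abs(np.diff(vals))
        pearson = np.corrcoef(x.values, y.values)[0, 1]
        assert abs(vals[-1] - pearson) < 1e-4
        assert np.all(np.isfinite(vals))
        # small change in w changes s little at the top of the ladder
        assert diffs[-1] < 1e-2

    def test_raw_bilinear_form_toggle(self):
        labels = ["A", "B"]
        x = SpatialProfile(labels, np.array([2.0, 1.0]))
        Cn = np.array([[0.0, 1.0], [1.0, 0.0]])
        raw = spatial_correlation(x, x, Cn, w=10.0, normalize_profiles=False)
        M = (Cn + 10.0 * np.eye(2)) / 11.0
        assert raw == pytest.approx(float(x.values @ M @ x.values), abs=1e-12)


class TestCombinedObjective:
    def test_perfect_fit_in_identity_limit(self, small_graph, grid):
        db, prof = _db_pair(small_graph, grid)
        Cn = row_degree_normalize(small_graph.C)
        val = combined_objective(db, prof, db, prof, Cn, ObjectiveConfig(w=1e6))
        assert val.combined == pytest.approx(2.0, abs=1e-5)
        assert val.combined == val.spectral_r + val.spatial_s

    def test_spectral_only_ignores_profiles(self, small_graph, grid):
        db, prof = _db_pair(small_graph, grid)
        Cn = row_degree_normalize(small_graph.C)
        cfg = ObjectiveConfig(cost_mode="spectral_only")
        rng = np.random.default_rng(9)
        perm = rng.permutation(small_graph.n_regions)
        prof2 = type(prof)(prof.region_labels, prof.values[perm])
        v1 = combined_objective(db, prof, db, prof, Cn, cfg)
        v2 = combined_objective(db, prof2, db, prof, Cn, cfg)
        assert v1.cost() == v2.cost() == v1.spectral_r

    def test_modes_expose_their_own_term(self, small_graph, grid):
        db, prof = _db_pair(small_graph, grid)
        Cn = row_degree_normalize(small_graph.C)
        for mode in ("combined", "spectral_only", "spatial_only"):
            v = combined_objective(db, prof, db, prof, Cn, ObjectiveConfig(cost_mode=mode))
            expected = {
                "combined": v.combined,
                "spectral_only": v.spectral_r,
                "spatial_only": v.spatial_s,
            }[mode]
            assert v.cost() == expected

    def test_sum_of_components(self):
        from brainsgm.objective import ObjectiveValue

        v = ObjectiveValue(0.9, np.array([0.9]), 0.5, 1.4)
        assert v.combined == pytest.approx(0.9 + 0.5)


class TestFisherZ:
    @pytest.mark.parametrize("r, z", [(0.0, 0.0), (0.5, 0.5493)])
    def test_known_values(self, r, z):
        assert fisher_z(r) == pytest.approx(z, abs=1e-4)

    def test_odd_function(self):
        for r in (0.1, 0.6, 0.95):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-15)

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)
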