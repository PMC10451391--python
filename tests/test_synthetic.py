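import math

import numpy as np
import pytest

import corneafit as cf


class TestGroundTruthConsistency:
    def test_morphometry_self_consistent(self, noiseless_pair):
        _, truth = noiseless_pair
        m = cf.morpho_parameters(cf.to_canonical_ellipsoid(truth.coefficients))
        t = truth.morphometry
        assert m.rx == pytest.approx(t.rx, abs=1e-10)
        assert m.ry == pytest.approx(t.ry, abs=1e-10)
        assert m.qx == pytest.approx(t.qx, abs=1e-10)
        assert m.qy == pytest.approx(t.qy, abs=1e-10)

    def test_prescribed_parameters_realized_exactly(self, noiseless_pair):
        _, truth = noiseless_pair
        assert truth.morphometry.rx == pytest.approx(7.8, abs=1e-12)
        assert truth.morphometry.qx == pytest.approx(-0.3, abs=1e-12)

    def test_mismatched_c_uses_geometric_mean(self):
        """Distinct x/y conics share one c-axis; truth reflects realized axes."""
        spec = cf.SyntheticSpec(rx=7.8, ry=7.4, qx=-0.3, qy=-0.2, seed=1)
        _, truth = cf.make_ellipsoid_grid(spec)
        a, b, c = truth.ellipsoid.semi_axes
        assert c == pytest.approx(math.sqrt((7.8 / 0.7) * (7.4 / 0.8)), rel=1e-12)
        assert truth.morphometry.rx == pytest.approx(a * a / c, rel=1e-12)
        assert truth.morphometry.qy == pytest.approx((b / c) ** 2 - 1, rel=1e-12)

    def test_direct_fit_recovers_truth(self):
        spec = cf.SyntheticSpec(rx=7.6, ry=7.9, qx=-0.25, qy=-0.35,
                                tilt_deg=1.5, apex_offset=(0.1, -0.1, 0.05),
                                seed=6)
        grid, truth = cf.make_ellipsoid_grid(spec)
        res = cf.fit_direct_linear(cf.polar_to_cartesian(grid))
        dev = min(np.max(np.abs(res.coefficients.array - truth.coefficients.array)),
                  np.max(np.abs(res.coefficients.array + truth.coefficients.array)))
        assert dev < 1e-8


class TestNoiseAndDropout:
    def test_dropout_count_and_determinism(self):
        spec = cf.SyntheticSpec(dropout_fraction=0.3, seed=13)
        g1, _ = cf.make_ellipsoid_grid(spec)
        g2, _ = cf.make_ellipsoid_grid(spec)
        assert g1.n_sentinels == math.floor(0.3 * 6144)
        assert np.array_equal(g1.elevations, g2.elevations)

    def test_wedge_dropout_contiguous(self):
        spec = cf.SyntheticSpec(dropout_fraction=0.25, dropout_mode="wedge", seed=3)
        grid, _ = cf.make_ellipsoid_grid(spec)
        dropped_cols = np.flatnonzero(grid.sentinel_mask.all(axis=0))
        assert len(dropped_cols) == round(0.25 * 256)

    def test_noise_variance_matches_sigma(self):
        sigma = 0.005
        clean, _ = cf.make_ellipsoid_grid(cf.SyntheticSpec(seed=17))
        noisy, _ = cf.make_ellipsoid_grid(cf.SyntheticSpec(noise_sigma=sigma, seed=17))
        diff = noisy.elevations - clean.elevations
        assert diff.size >= 4000
        assert np.var(diff) == pytest.approx(sigma ** 2, rel=0.1)

    def test_truth_mse_on_noisy_cloud_is_sigma_squared(self, noisy_pair, noisy_cloud):
        _, truth = noisy_pair
        mse, _ = cf.elevation_mse(truth.coefficients, noisy_cloud)
        assert mse == pytest.approx(0.005 ** 2, rel=0.2)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            cf.SyntheticSpec(qx=-1.0)
        with pytest.raises(ValueError):
            cf.SyntheticSpec(dropout_fraction=1.0)
        with pytest.raises(ValueError):
            cf.SyntheticSpec(rx=-1.0)
        with pytest.raises(ValueError):
            cf.SyntheticSpec(dropout_mode="sideways")


class TestCone:
    def test_zero_amplitude_is_identity(self, noiseless_pair):
        grid, _ = noiseless_pair
        bumped = cf.add_cone(grid, amplitude=0.0, width=1.5, center=(1.0, 1.0))
        assert np.array_equal(bumped.elevations, grid.elevations)

    def test_far_bump_is_negligible(self, noiseless_pair):
        grid, _ = noiseless_pair
        bumped = cf.add_cone(grid, amplitude=0.05, width=0.5, center=(50.0, 0.0))
        assert np.max(np.abs(bumped.elevations - grid.elevations)) < 1e-12

    def test_mse_grows_monotonically_with_amplitude(self, noiseless_pair):
        grid, truth = noiseless_pair
        mses = []
        for amp in (0.01, 0.03, 0.05, 0.10):
            bumped = cf.add_cone(grid, amplitude=amp, width=1.5, center=(1.0, -1.0))
            mse, _ = cf.elevation_mse(truth.coefficients,
                                      cf.polar_to_cartesian(bumped))
            mses.append(mse)
        assert all(a < b for a, b in zip(mses, mses[1:]))

    def test_sentinels_untouched(self):
        grid, _ = cf.make_ellipsoid_grid(
            cf.SyntheticSpec(dropout_fraction=0.2, seed=8))
        bumped = cf.add_cone(grid, amplitude=0.1, width=1.5, center=(0.0, 0.0))
        assert np.array_equal(bumped.sentinel_mask, grid.sentinel_mask)


class TestCohorts:
    def test_deterministic(self):
        a = cf.make_cohort(4, "control", seed=1)
        b = cf.make_cohort(4, "control", seed=1)
        for (ga_, _), (gb, _) in zip(a, b):
            assert np.array_equal(ga_.elevations, gb.elevations)

    def test_grade_orders_asphericity(self):
        control = cf.make_cohort(10, "control", seed=2)
        ak34 = cf.make_cohort(10, "ak34", seed=2)
        q_control = np.mean([t.morphometry.qx for _, t in control])
        q_ak34 = np.mean([t.morphometry.qx for _, t in ak34])
        assert q_ak34 < q_control

    def test_grids_round_trip_csv(self, tmp_path):
        for i, (grid, _) in enumerate(cf.make_cohort(2, "ak1", seed=3)):
            p = tmp_path / f"g{i}.csv"
            cf.write_polar_csv(grid, p)
            back = cf.read_polar_csv(p)
            assert np.array_equal(back.elevations, grid.elevations)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            cf.make_cohort(0, "control")
        with pytest.raises(ValueError):
            cf.make_cohort(1, "grade9")
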