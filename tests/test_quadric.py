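import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corneafit as cf
from corneafit.quadric import COEFF_NAMES, normalize_coefficients

UNIT_SPHERE = cf.QuadricCoefficients.from_values(
    0.5, 0, 0, 0, 0.5, 0, 0, 0.5, 0, -0.5)
SPHERE_R10 = cf.QuadricCoefficients.from_values(
    1, 0, 0, 0, 1, 0, 0, 1, 0, -100.0)


def monomial_sum(vec, p):
    """Independent term-by-term oracle for Q(x, y, z)."""
    x, y, z = p
    terms = [x * x, x * y, x * z, x, y * y, y * z, y, z * z, z, 1.0]
    return sum(a * t for a, t in zip(vec, terms))


coeff_vectors = st.lists(
    st.floats(-5, 5, allow_nan=False), min_size=10, max_size=10,
).filter(lambda v: np.linalg.norm(v) > 1e-6)
points = st.tuples(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))


class TestEvaluate:
    def test_point_on_unit_sphere(self):
        assert cf.evaluate_quadric(UNIT_SPHERE, np.array([1.0, 0, 0])) == pytest.approx(0.0)

    def test_interior_is_negative(self):
        assert cf.evaluate_quadric(UNIT_SPHERE, np.zeros(3)) < 0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(coeff_vectors, points)
    def test_matches_monomial_sum(self, vec, p):
        c = cf.QuadricCoefficients(np.array(vec))
        expected = monomial_sum(c.array, p)
        assert cf.evaluate_quadric(c, np.array(p)) == pytest.approx(expected, abs=1e-10)


class TestNormalization:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(coeff_vectors, st.floats(0.01, 100.0))
    def test_scale_invariant(self, vec, k):
        a = cf.QuadricCoefficients(np.array(vec))
        b = cf.QuadricCoefficients(k * np.array(vec))
        np.testing.assert_allclose(a.array, b.array, atol=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(coeff_vectors)
    def test_unit_norm_and_sign(self, vec):
        arr = cf.QuadricCoefficients(np.array(vec)).array
        assert np.linalg.norm(arr) == pytest.approx(1.0)
        assert arr[COEFF_NAMES.index("a33")] >= 0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize_coefficients(np.zeros(10))

    def test_dict_round_trip(self):
        d = SPHERE_R10.to_dict()
        assert set(d) == set(COEFF_NAMES)
        back = cf.QuadricCoefficients.from_dict(d)
        np.testing.assert_array_equal(back.array, SPHERE_R10.array)


class TestAlgebraicFitness:
    def test_zero_on_surface(self, noiseless_pair, noiseless_cloud):
        _, truth = noiseless_pair
        assert cf.algebraic_fitness(truth.coefficients, noiseless_cloud) < 1e-25

    def test_matches_loop_oracle(self, rng):
        pts = rng.normal(size=(5, 3))
        c = cf.QuadricCoefficients(rng.normal(size=10))
        expected = np.mean([monomial_sum(c.array, p) ** 2 for p in pts])
        cloud = cf.PointCloud(points=pts)
        assert cf.algebraic_fitness(c, cloud) == pytest.approx(expected, rel=1e-12)

    def test_empty_cloud_raises(self):
        with pytest.raises(cf.EmptyCloudError):
            cf.algebraic_fitness(UNIT_SPHERE, np.empty((0, 3)))


class TestSolveElevation:
    def test_sphere_branch_selection(self):
        z = cf.solve_elevation(SPHERE_R10, 0.0, 0.0, z_ref=9.0)
        assert float(z) == pytest.approx(10.0, abs=1e-12)
        z = cf.solve_elevation(SPHERE_R10, 0.0, 0.0, z_ref=-9.0)
        assert float(z) == pytest.approx(-10.0, abs=1e-12)

    def test_tangent_double_root(self):
        z = cf.solve_elevation(SPHERE_R10, 6.0, 8.0, z_ref=1.0)
        assert float(z) == pytest.approx(0.0, abs=1e-6)

    def test_no_real_root_is_nan(self):
        assert np.isnan(float(cf.solve_elevation(SPHERE_R10, 11.0, 0.0, z_ref=0.0)))

    def test_recovers_ellipsoid_elevations(self, noiseless_pair, noiseless_cloud):
        _, truth = noiseless_pair
        pts = noiseless_cloud.points
        z = cf.solve_elevation(truth.coefficients, pts[:, 0], pts[:, 1],
                               z_ref=pts[:, 2])
        np.testing.assert_allclose(z, pts[:, 2], atol=1e-10)

    def test_linear_case(self):
        # plane-like z-equation: a33 = 0, a30 dominates
        c = cf.QuadricCoefficients.from_values(1e-3, 0, 0, 0, 1e-3, 0, 0, 0, 1.0, -2.0)
        z = float(cf.solve_elevation(c, 1.0, 1.0, z_ref=0.0))
        # a33 z^2 term absent: z = -(a11 + a22 + a00)/a30 for x=y=1
        a = c.array
        assert z == pytest.approx(-(a[0] + a[4] + a[9]) / a[8], rel=1e-12)


class TestElevationMse:
    def test_exact_surface_zero(self, noiseless_pair, noiseless_cloud):
        _, truth = noiseless_pair
        mse, unresolved = cf.elevation_mse(truth.coefficients, noiseless_cloud)
        assert mse < 1e-20
        assert unresolved == 0

    def test_constant_offset_gives_delta_squared(self, noiseless_pair, noiseless_cloud):
        _, truth = noiseless_pair
        delta = 0.003
        shifted = cf.PointCloud(points=noiseless_cloud.points + [0, 0, delta],
                                source_node_ids=noiseless_cloud.source_node_ids)
        mse, _ = cf.elevation_mse(truth.coefficients, shifted)
        assert mse == pytest.approx(delta ** 2, rel=1e-6)

    def test_noise_floor_is_sigma_squared(self, noisy_pair, noisy_cloud):
        _, truth = noisy_pair
        mse, _ = cf.elevation_mse(truth.coefficients, noisy_cloud)
        assert mse == pytest.approx(0.005 ** 2, rel=0.2)

    def test_rotation_invariance_about_z(self, noisy_pair, noisy_cloud):
        """Rotating both cloud and quadric about z leaves the MSE unchanged."""
        _, truth = noisy_pair
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        rot_pts = noisy_cloud.points @ R.T
        A, b = truth.coefficients.quadratic_form(), truth.coefficients.linear_part()
        A2, b2 = R @ A @ R.T, R @ b
        from corneafit.quadric import coefficients_from_blocks
        c2 = cf.QuadricCoefficients(
            coefficients_from_blocks(A2, b2, truth.coefficients.constant()))
        mse1, _ = cf.elevation_mse(truth.coefficients, noisy_cloud)
        mse2, _ = cf.elevation_mse(c2, cf.PointCloud(points=rot_pts))
        assert mse2 == pytest.approx(mse1, rel=1e-9)

    def test_surface_missing_cloud_raises(self):
        cloud = cf.PointCloud(points=np.column_stack(
            [np.full(20, 50.0), np.zeros(20), np.zeros(20)]))  # far outside sphere
        with pytest.raises(cf.SurfaceMissError):
            cf.elevation_mse(SPHERE_R10, cloud)
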