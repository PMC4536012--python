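import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.special import sph_harm_y

from calcatlas.spharm import (
    BasisSpec,
    SphericalSamples,
    eval_basis,
    fibonacci_directions,
    fit_coefficients,
    fit_sphere,
    radius_function,
    reconstruct,
    sphere_quadrature,
    to_cartesian,
    to_spherical,
)

SQRT_4PI = np.sqrt(4 * np.pi)


class TestBasisSpec:
    @pytest.mark.parametrize("order", [0, 1, 4, 11])
    def test_coefficient_count(self, order):
        spec = BasisSpec(order)
        assert spec.n_coefficients == (order + 1) ** 2
        assert len(spec.degrees_orders) == spec.n_coefficients
        degrees = [l for l, _ in spec.degrees_orders]
        assert degrees == sorted(degrees)
        for l in range(order + 1):
            ms = [m for ll, m in spec.degrees_orders if ll == l]
            assert ms == list(range(-l, l + 1))


class TestSphereFit:
    def test_exact_axis_aligned_sphere(self):
        c = np.array([1.0, 2.0, 3.0])
        pts = c + 5.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
        )
        fit = fit_sphere(pts)
        np.testing.assert_allclose(fit.center, c, atol=1e-12)
        assert fit.radius == pytest.approx(5.0)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)

    def test_unit_octahedron(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        fit = fit_sphere(pts)
        np.testing.assert_allclose(fit.center, 0, atol=1e-12)
        assert fit.radius == pytest.approx(1.0)

    def test_noisy_sphere_matches_nonlinear_refinement_oracle(self):
        rng = np.random.default_rng(8)
        theta, phi = fibonacci_directions(500)
        radius = 10.0 * (1 + 0.01 * rng.normal(size=500))
        pts = to_cartesian(theta, phi, radius) + np.array([3.0, -2.0, 1.0])
        fit = fit_sphere(pts)
        tol = 3 * 0.01 * 10.0 / np.sqrt(500)

        def resid(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        oracle = least_squares(resid, x0=np.array([0, 0, 0, 5.0])).x
        np.testing.assert_allclose(fit.center, oracle[:3], atol=tol)
        assert abs(fit.radius - oracle[3]) < tol

    def test_coplanar_rejected(self):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0) ** 2, np.zeros(6)])
        with pytest.raises(ValueError):
            fit_sphere(pts)


class TestSphericalConversion:
    @pytest.mark.parametrize(
        "point, expected",
        [((0, 0, 1), (0.0, np.pi / 2, 1.0)), ((1, 0, 0), (0.0, 0.0, 1.0))],
    )
    def test_axis_points(self, point, expected):
        samples = to_spherical(np.array([point], float), origin=np.zeros(3))
        assert samples.theta[0] == pytest.approx(expected[0], abs=1e-12)
        assert samples.phi[0] == pytest.approx(expected[1], abs=1e-12)
        assert samples.radius[0] == pytest.approx(expected[2])

    def test_centroid_origin_and_ranges(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(size=(200, 3)) + 5.0
        samples = to_spherical(cloud)
        np.testing.assert_allclose(samples.origin, cloud.mean(axis=0))
        assert samples.scale == pytest.approx(samples.radius.max())
        assert np.all((samples.theta >= -np.pi) & (samples.theta < np.pi))
        assert np.all(np.abs(samples.phi) <= np.pi / 2)

    def test_roundtrip(self):
        rng = np.random.default_rng(2)
        cloud = rng.normal(size=(300, 3)) * [3, 2, 1] + [10, -4, 2]
        s = to_spherical(cloud)
        back = to_cartesian(s.theta, s.phi, s.radius, origin=s.origin)
        np.testing.assert_allclose(back, cloud, rtol=1e-12, atol=1e-12)

    def test_point_at_origin_rejected(self):
        cloud = np.array([[0.0, 0, 0], [1, 0, 0], [-1, 0, 0]])
        with pytest.raises(ValueError):
            to_spherical(cloud, origin=np.zeros(3))


class TestBasisValues:
    def test_constant_and_first_degree(self):
        assert eval_basis(0.3, -0.7, 0)[0, 0] == pytest.approx(1 / SQRT_4PI)
        # y_10 at the north pole (elevation pi/2)
        assert eval_basis(0.0, np.pi / 2, 1)[0, 2] == pytest.approx(np.sqrt(3 / (4 * np.pi)))

    @pytest.mark.parametrize("order", [4, 8])
    def test_orthonormal_on_quadrature(self, order):
        theta, phi, w = sphere_quadrature(order)
        basis = eval_basis(theta, phi, order)
        gram = (basis * w[:, None]).T @ basis
        assert np.abs(gram - np.eye(basis.shape[1])).max() < 1e-6

    def test_matches_scipy_complex_harmonics(self):
        # independent oracle: real combinations of scipy's complex Y_lm
        rng = np.random.default_rng(3)
        theta = rng.uniform(-np.pi, np.pi, 50)
        phi = rng.uniform(-np.pi / 2, np.pi / 2, 50)
        basis = eval_basis(theta, phi, 5)
        polar = np.pi / 2 - phi
        for q, (l, m) in enumerate(BasisSpec(5).degrees_orders):
            y = sph_harm_y(l, abs(m), polar, theta)
            if m == 0:
                expected = y.real
            elif m > 0:
                expected = np.sqrt(2) * y.real
            else:
                expected = np.sqrt(2) * y.imag
            np.testing.assert_allclose(basis[:, q], expected, atol=1e-12)


class TestFitAndReconstruct:
    def test_unit_sphere_forces_pure_constant(self):
        theta, phi = fibonacci_directions(400)
        samples = SphericalSamples(theta, phi, np.ones(400), scale=1.0, origin=np.zeros(3))
        coeffs = fit_coefficients(samples, 2)
        assert coeffs.values[0] == pytest.approx(SQRT_4PI, abs=1e-10)
        np.testing.assert_allclose(coeffs.values[1:], 0, atol=1e-10)

    def test_noiseless_parameter_recovery(self):
        rng = np.random.default_rng(4)
        truth = rng.normal(scale=0.05, size=16)
        truth[0] = SQRT_4PI
        theta, phi = fibonacci_directions(2000)
        radius = eval_basis(theta, phi, 3) @ truth
        samples = SphericalSamples(theta, phi, radius, scale=1.0, origin=np.zeros(3))
        coeffs = fit_coefficients(samples, 3)
        np.testing.assert_allclose(coeffs.values, truth, atol=1e-8)
        assert coeffs.rss < 1e-10

    def test_noisy_recovery_rmse(self):
        theta, phi = fibonacci_directions(2000)
        rmses = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = rng.normal(scale=0.05, size=16)
            truth[0] = SQRT_4PI
            radius = eval_basis(theta, phi, 3) @ truth + 0.01 * rng.normal(size=2000)
            samples = SphericalSamples(theta, phi, radius, scale=1.0, origin=np.zeros(3))
            est = fit_coefficients(samples, 3).values
            rmses.append(np.sqrt(np.mean((est - truth) ** 2)))
        assert np.mean(rmses) < 0.01

    def test_reconstruct_sphere_and_residual_consistency(self):
        theta, phi = fibonacci_directions(500)
        samples = SphericalSamples(theta, phi, np.full(500, 7.0), scale=7.0, origin=np.zeros(3))
        coeffs = fit_coefficients(samples, 2)
        pts = reconstruct(coeffs, theta, phi)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 7.0, atol=1e-9)

    def test_fit_then_reconstruct_within_residual(self):
        rng = np.random.default_rng(6)
        theta, phi = fibonacci_directions(800)
        radius = 5.0 + 0.2 * rng.normal(size=800)
        samples = SphericalSamples(theta, phi, radius, scale=radius.max(), origin=np.zeros(3))
        coeffs = fit_coefficients(samples, 4)
        fitted = radius_function(coeffs, theta, phi)
        assert ((radius - fitted) ** 2).sum() == pytest.approx(coeffs.rss * samples.scale**2)

    def test_ellipsoid_radial_error_below_one_percent(self):
        theta, phi = fibonacci_directions(3000)
        a, b, c = 1.2, 1.0, 0.8
        direction = to_cartesian(theta, phi, np.ones(3000))
        radius = 1.0 / np.sqrt(
            (direction[:, 0] / a) ** 2 + (direction[:, 1] / b) ** 2 + (direction[:, 2] / c) ** 2
        )
        samples = SphericalSamples(theta, phi, radius, scale=radius.max(), origin=np.zeros(3))
        coeffs = fit_coefficients(samples, 6)
        err = np.abs(radius_function(coeffs, theta, phi) - radius)
        assert err.max() < 0.01 * radius.mean()

    def test_nesting_never_increases_rss(self):
        rng = np.random.default_rng(7)
        theta, phi = fibonacci_directions(1000)
        radius = 1.0 + 0.1 * rng.normal(size=1000)
        samples = SphericalSamples(theta, phi, radius, scale=1.0, origin=np.zeros(3))
        rss = [fit_coefficients(samples, L).rss for L in range(6)]
        assert all(b <= a + 1e-12 for a, b in zip(rss, rss[1:]))

    def test_per_degree_energy_invariant_under_z_rotation(self):
        rng = np.random.default_rng(9)
        truth = rng.normal(scale=0.05, size=25)
        truth[0] = SQRT_4PI
        theta, phi = fibonacci_directions(2000)
        radius = eval_basis(theta, phi, 4) @ truth
        rotated = np.mod(theta + 1.1 + np.pi, 2 * np.pi) - np.pi
        c0 = fit_coefficients(SphericalSamples(theta, phi, radius, 1.0, np.zeros(3)), 4).values
        c1 = fit_coefficients(SphericalSamples(rotated, phi, radius, 1.0, np.zeros(3)), 4).values
        for l in range(5):
            sl = slice(l**2, (l + 1) ** 2)
            assert np.sum(c1[sl] ** 2) == pytest.approx(np.sum(c0[sl] ** 2), abs=1e-6)

    def test_insufficient_samples_rejected(self):
        theta, phi = fibonacci_directions(8)
        samples = SphericalSamples(theta, phi, np.ones(8), scale=1.0, origin=np.zeros(3))
        with pytest.raises(ValueError):
            fit_coefficients(samples, 2)

    def test_clustered_directions_rejected(self):
        theta = np.full(100, 0.3)
        phi = np.full(100, 0.2)
        samples = SphericalSamples(theta, phi, np.ones(100), scale=1.0, origin=np.zeros(3))
        with pytest.raises(ValueError, match="rank"):
            fit_coefficients(samples, 3)
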