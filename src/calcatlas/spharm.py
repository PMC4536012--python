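r"""Real spherical-harmonics (SPHARM) radius expansion of a star-shaped cloud.

The canonical point cloud is recentred at its centre of mass, converted to
spherical coordinates (azimuth theta in [-pi, pi), elevation phi in
[-pi/2, pi/2], radius R_d > 0) and scaled by R_s = max(R_d).  The radius
ratio is then expanded in real, fully normalized spherical harmonics

    R_d / R_s = sum_{l=0..L} sum_{m=-l..l} c_lm y_lm(theta_d, phi_d)

with y_lm built from the normalization N_lm = sqrt((2l+1)(l-m)! / (4pi
(l+m)!)) and the associated Legendre functions P_lm (Condon–Shortley phase
included), evaluated at the polar angle pi/2 - phi:

    y_lm = sqrt(2) N_lm P_lm(cos pol) cos(m theta)   (m > 0)
         = sqrt(2) N_l|m| P_l|m|(cos pol) sin(|m| theta)   (m < 0)
         =         N_l0 P_l0(cos pol)   (m = 0)

The basis is orthonormal over the sphere; coefficients are estimated by
linear least squares.  P_lm is evaluated with the stable fully normalized
three-term recurrence (direct differentiation of the Rodrigues form
overflows around l ~ 11).  Coefficient ordering is q = 1..(L+1)^2 with
l = 0..L and m running -l..l within each degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "BasisSpec",
    "SphereFit",
    "SphericalSamples",
    "SpharmCoefficients",
    "fit_sphere",
    "to_spherical",
    "to_cartesian",
    "eval_basis",
    "fit_coefficients",
    "reconstruct",
    "sphere_quadrature",
    "fibonacci_directions",
]

COND_WARN_THRESHOLD = 1e8


@dataclass(frozen=True)
class BasisSpec:
    """Index bookkeeping for a real SPHARM basis truncated at degree L."""

    order: int

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("basis order must be >= 0")

    @property
    def n_coefficients(self) -> int:
        return (self.order + 1) ** 2

    @property
    def degrees_orders(self) -> list[tuple[int, int]]:
        """(l, m) for q = 1..Q: l ascending, m from -l to l within each l."""
        return [(l, m) for l in range(self.order + 1) for m in range(-l, l + 1)]


@dataclass(frozen=True)
class SphereFit:
    """Algebraic best-fit sphere: centre (mm), radius R_BS (mm), residuals."""

    center: np.ndarray
    radius: float
    residuals: np.ndarray


@dataclass
class SphericalSamples:
    """Spherical samples of a cloud about its centre of mass.

    theta: azimuth in [-pi, pi); phi: elevation in [-pi/2, pi/2];
    radius: R_d in mm (all > 0); scale: R_s = max(R_d); origin: the centre
    of mass (unit masses) in the frame the cloud arrived in.
    """

    theta: np.ndarray
    phi: np.ndarray
    radius: np.ndarray
    scale: float
    origin: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.theta.size


@dataclass
class SpharmCoefficients:
    """Estimated expansion coefficients c_q (radius-ratio units) at order L."""

    values: np.ndarray
    scale: float
    order: int
    rss: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.size != (self.order + 1) ** 2:
            raise ValueError("coefficient vector length must be (L+1)^2")


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Best sphere through a cloud, linear-in-parameters least squares.

    Solves ``x^2+y^2+z^2 = 2 a x + 2 b y + 2 c z + d`` for (a, b, c, d);
    exact for noiseless spherical data.  Requires >= 4 non-coplanar points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 4:
        raise ValueError("sphere fit needs an N x 3 cloud with N >= 4")
    design = np.column_stack([2.0 * points, np.ones(len(points))])
    rhs = (points**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) cloud: sphere fit is rank-deficient")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))
    residuals = np.linalg.norm(points - center, axis=1) - radius
    return SphereFit(center=center, radius=radius, residuals=residuals)


def to_spherical(points: np.ndarray, origin: np.ndarray | None = None) -> SphericalSamples:
    """Recentre a cloud at its centre of mass and convert to spherical samples.

    With unit point masses the centre of mass is the coordinate mean.  An
    explicit ``origin`` overrides the centroid (used e.g. for diagnostics
    about the best-sphere centre).  Raises if any point coincides with the
    origin (its direction is undefined).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("expected an N x 3 cloud")
    origin = points.mean(axis=0) if origin is None else np.asarray(origin, dtype=float)
    rel = points - origin
    radius = np.linalg.norm(rel, axis=1)
    if np.any(radius <= 0):
        raise ValueError("a point coincides with the origin; direction undefined")
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    theta = np.where(theta >= np.pi, theta - 2 * np.pi, theta)  # keep [-pi, pi)
    phi = np.arcsin(np.clip(rel[:, 2] / radius, -1.0, 1.0))
    return SphericalSamples(
        theta=theta, phi=phi, radius=radius, scale=float(radius.max()), origin=origin
    )


def to_cartesian(
    theta: np.ndarray, phi: np.ndarray, radius: np.ndarray, origin: np.ndarray | None = None
) -> np.ndarray:
    """Inverse of :func:`to_spherical` (azimuth/elevation/radius -> x, y, z)."""
    theta, phi, radius = np.broadcast_arrays(theta, phi, radius)
    xyz = np.column_stack(
        [
            radius * np.cos(phi) * np.cos(theta),
            radius * np.cos(phi) * np.sin(theta),
            radius * np.sin(phi),
        ]
    )
    if origin is not None:
        xyz = xyz + np.asarray(origin, dtype=float)
    return xyz


def _normalized_legendre(L: int, x: np.ndarray) -> np.ndarray:
    """Fully normalized associated Legendre values N_lm * P_lm(x).

    Returns an array of shape (L+1, L+1, len(x)) indexed [l, m]; entries
    with m > l are zero.  Uses the standard stable recurrences: the
    diagonal ``Ptilde_mm = -sqrt((2m+1)/(2m)) s Ptilde_{m-1,m-1}`` carries
    the Condon–Shortley phase, and degrees above the diagonal follow the
    three-term recurrence in l.
    """
    x = np.asarray(x, dtype=float)
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    out = np.zeros((L + 1, L + 1, x.size))
    out[0, 0] = 1.0 / np.sqrt(4.0 * np.pi)
    for m in range(1, L + 1):
        out[m, m] = -np.sqrt((2.0 * m + 1.0) / (2.0 * m)) * s * out[m - 1, m - 1]
    for m in range(0, L):
        out[m + 1, m] = x * np.sqrt(2.0 * m + 3.0) * out[m, m]
    for m in range(0, L + 1):
        for l in range(m + 2, L + 1):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            out[l, m] = a * (x * out[l - 1, m] - b * out[l - 2, m])
    return out


def eval_basis(theta: np.ndarray, phi: np.ndarray, order: int) -> np.ndarray:
    """Design matrix of real SPHARM basis values, shape (D, (L+1)^2).

    ``theta`` is azimuth, ``phi`` elevation; the Legendre argument is
    cos(polar) = cos(pi/2 - phi) = sin(phi).  Columns follow the q ordering
    of :class:`BasisSpec`.
    """
    spec = BasisSpec(order)
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).reshape(-1)
    phi = np.atleast_1d(np.asarray(phi, dtype=float)).reshape(-1)
    if theta.size != phi.size:
        raise ValueError("theta and phi must have the same length")
    plm = _normalized_legendre(order, np.sin(phi))
    cols = np.empty((theta.size, spec.n_coefficients))
    sqrt2 = np.sqrt(2.0)
    for q, (l, m) in enumerate(spec.degrees_orders):
        if m == 0:
            cols[:, q] = plm[l, 0]
        elif m > 0:
            cols[:, q] = sqrt2 * plm[l, m] * np.cos(m * theta)
        else:
            cols[:, q] = sqrt2 * plm[l, -m] * np.sin(-m * theta)
    return cols


def fit_coefficients(samples: SphericalSamples, order: int) -> SpharmCoefficients:
    """Least-squares SPHARM coefficients of the radius ratio R_d / R_s.

    Solved by SVD-based least squares (rank-revealing); warns when the
    design condition number exceeds 1e8 and raises when the design is
    rank-deficient (clustered sample directions).
    """
    q = (order + 1) ** 2
    if samples.n_samples < q:
        raise ValueError(
            f"need at least (L+1)^2 = {q} samples for order {order}, got {samples.n_samples}"
        )
    design = eval_basis(samples.theta, samples.phi, order)
    target = samples.radius / samples.scale
    sol, _, rank, sv = scipy.linalg.lstsq(design, target, lapack_driver="gelsd")
    if rank < q:
        raise ValueError(
            f"rank-deficient SPHARM design (rank {rank} < {q}): "
            "sample directions do not cover the sphere"
        )
    cond = sv[0] / sv[-1]
    if cond > COND_WARN_THRESHOLD:
        warnings.warn(
            f"ill-conditioned SPHARM design (cond ~ {cond:.2e})", RuntimeWarning, stacklevel=2
        )
    rss = float(((target - design @ sol) ** 2).sum())
    return SpharmCoefficients(values=sol, scale=samples.scale, order=order, rss=rss)


def reconstruct(
    coeffs: SpharmCoefficients,
    theta: np.ndarray,
    phi: np.ndarray,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Cartesian surface points at the given directions from the expansion.

    ``R_hat(theta, phi) = R_s * sum_q c_q y_q(theta, phi)``; pass ``origin``
    to translate the reconstruction back to the starting frame.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).reshape(-1)
    phi = np.atleast_1d(np.asarray(phi, dtype=float)).reshape(-1)
    radius = coeffs.scale * (eval_basis(theta, phi, coeffs.order) @ coeffs.values)
    return to_cartesian(theta, phi, radius, origin=origin)


def radius_function(coeffs: SpharmCoefficients, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Radius R_hat(theta, phi) in mm at the given directions."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).reshape(-1)
    phi = np.atleast_1d(np.asarray(phi, dtype=float)).reshape(-1)
    return coeffs.scale * (eval_basis(theta, phi, coeffs.order) @ coeffs.values)


def sphere_quadrature(order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Product quadrature (theta, phi, weights) exact for harmonics to 2*order.

    Gauss–Legendre nodes in cos(polar) crossed with a uniform azimuth grid;
    integrates products y_lm * y_l'm' exactly for l, l' <= order, so the
    Gram matrix of the basis evaluates to the identity at machine precision.
    """
    n_pol = order + 1
    n_az = 4 * order + 2 if order > 0 else 2
    nodes, wts = np.polynomial.legendre.leggauss(n_pol)
    az = -np.pi + 2.0 * np.pi * np.arange(n_az) / n_az
    theta = np.repeat(az, n_pol)
    phi = np.tile(np.arcsin(nodes), n_az)  # cos(polar) = sin(elevation)
    weights = np.tile(wts, n_az) * (2.0 * np.pi / n_az)
    return theta, phi, weights


def fibonacci_directions(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quasi-uniform directions (theta azimuth, phi elevation).

    Fibonacci spiral on the sphere; seed-independent so repeated fits share
    identical, well-conditioned designs.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.mod(2.0 * np.pi * i / golden + np.pi, 2.0 * np.pi) - np.pi
    phi = np.arcsin(np.clip(z, -1.0, 1.0))
    return theta, phi
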