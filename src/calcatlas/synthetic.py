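"""Synthetic calcaneus-like populations with known ground truth.

Every pipeline stage is testable without scans: bones are star-shaped
closed surfaces drawn from a base SPHARM coefficient vector with
per-coefficient Gaussian population variability, sampled at a deterministic
quasi-uniform direction set, with planted landmarks at six fixed
well-separated directions and a known rigid misorientation per bone.  An
optional rasterizer voxelizes a bone into a blurred, noisy binary volume
with a guaranteed-interior seed so the segmentation stage can be exercised
end to end.

The base shape is a handcrafted smooth, elongated, asymmetric low-order
coefficient vector scaled so the synthetic calcaneal-axis length lands near
80 mm — desk-scale realism, not anatomy; landmark planting is by fixed
directions, not anatomical rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .pose import LANDMARK_NAMES, LandmarkSet
from .preprocessing import Volume
from .segmentation import SeedSpec
from .spharm import (
    BasisSpec,
    SpharmCoefficients,
    eval_basis,
    fibonacci_directions,
    to_cartesian,
)

__all__ = [
    "PopulationSpec",
    "SyntheticBone",
    "RasterizedBone",
    "base_coefficients",
    "landmark_directions",
    "generate_population",
    "rasterize",
]

BASE_ORDER = 4

# Nonzero entries of the base shape, (l, m) -> value in radius-ratio units.
# c_00 = sqrt(4 pi) gives unit mean radius; degree-1/2/3 terms elongate the
# shape along x, flatten it in z and break fore/aft and top/bottom symmetry
# so that no reflection or rotation maps the shape onto itself.
_BASE_LM = {
    (0, 0): 3.5449077018110318,  # sqrt(4 pi)
    (1, 1): 0.12,
    (1, 0): 0.06,
    (2, 0): -0.16,
    (2, 2): 0.42,
    (2, -1): 0.05,
    (3, 1): 0.08,
    (3, -2): 0.05,
    (3, 3): -0.04,
    (4, 0): 0.03,
    (4, 2): 0.04,
}

# Planted landmark directions (azimuth theta, elevation phi), radians.
# C/D anterior superior/inferior, E posterior, F posterior superior,
# A superior over the body, B lateral between A and C.
_LANDMARK_DIRECTIONS = {
    "A": (1.50, 1.20),
    "B": (0.65, 0.65),
    "C": (0.00, 0.35),
    "D": (0.00, -0.35),
    "E": (3.10, -0.05),
    "F": (2.90, 0.55),
}

# Scale radius giving a base-shape calcaneal axis length (LCA) near 80 mm.
DEFAULT_SCALE_RADIUS_MM = 34.0


def base_coefficients(order: int = BASE_ORDER) -> np.ndarray:
    """The handcrafted base coefficient vector at the given order (>= 4)."""
    if order < BASE_ORDER:
        raise ValueError(f"base shape requires order >= {BASE_ORDER}")
    spec = BasisSpec(order)
    values = np.zeros(spec.n_coefficients)
    for q, (l, m) in enumerate(spec.degrees_orders):
        if (l, m) in _BASE_LM:
            values[q] = _BASE_LM[(l, m)]
    return values


def landmark_directions() -> dict[str, tuple[float, float]]:
    """The six fixed planting directions (theta, phi) for landmarks A-F."""
    return dict(_LANDMARK_DIRECTIONS)


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reference cohort: 18 bones per side, mild
    per-coefficient population variability, sub-percent radial sampling
    noise, scale radii scattered around the desk-scale base.
    """

    n_bones: int = 18
    order: int = BASE_ORDER
    base: np.ndarray | None = None
    coefficient_sd: float | np.ndarray = 0.01
    scale_radius_mean: float = DEFAULT_SCALE_RADIUS_MM
    scale_radius_sd: float = 2.0
    radial_noise: float = 0.005
    n_directions: int = 2500
    mirror: bool = False
    misorient: bool = True
    seed: int = 0
    max_rejections: int = 100

    def __post_init__(self) -> None:
        if self.n_bones < 0:
            raise ValueError("n_bones must be >= 0")
        if np.any(np.asarray(self.coefficient_sd) < 0):
            raise ValueError("coefficient SDs must be >= 0")
        if self.radial_noise < 0 or self.scale_radius_sd < 0:
            raise ValueError("noise levels must be >= 0")

    def base_vector(self) -> np.ndarray:
        if self.base is not None:
            base = np.asarray(self.base, dtype=float).reshape(-1)
            if base.size != (self.order + 1) ** 2:
                raise ValueError("base vector length must be (order+1)^2")
            return base
        return base_coefficients(self.order)


@dataclass
class SyntheticBone:
    """One generated bone with its ground truth."""

    cloud: np.ndarray
    landmarks: LandmarkSet
    coefficients: np.ndarray
    scale_radius: float
    side: str
    rotation: np.ndarray
    translation: np.ndarray


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _surface_points(
    coefficients: np.ndarray, order: int, theta: np.ndarray, phi: np.ndarray, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    ratio = eval_basis(theta, phi, order) @ coefficients
    return to_cartesian(theta, phi, scale * ratio), ratio


def generate_population(spec: PopulationSpec) -> list[SyntheticBone]:
    """Draw a cohort of bones from the population model.

    Per bone: coefficients = base + Gaussian per-coefficient draws (redrawn
    up to ``max_rejections`` times if the surface is not star-shaped), the
    surface sampled at the deterministic spiral directions with radial
    noise, landmarks planted on the noiseless surface, then an optional
    random rigid misorientation.  With ``mirror`` set, each bone gets a
    mirrored twin (x negated before misorientation) sharing its coefficient
    draw, labelled 'left'.  Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.base_vector()
    sd = np.broadcast_to(np.asarray(spec.coefficient_sd, dtype=float), base.shape)
    theta, phi = fibonacci_directions(spec.n_directions)
    lm_theta = np.array([_LANDMARK_DIRECTIONS[n][0] for n in LANDMARK_NAMES])
    lm_phi = np.array([_LANDMARK_DIRECTIONS[n][1] for n in LANDMARK_NAMES])

    bones: list[SyntheticBone] = []
    for _ in range(spec.n_bones):
        for attempt in range(spec.max_rejections + 1):
            coeffs = base + sd * rng.normal(size=base.shape)
            ratio = eval_basis(theta, phi, spec.order) @ coeffs
            if np.all(ratio > 0):
                break
        else:
            raise RuntimeError(
                f"no star-shaped draw within {spec.max_rejections} rejections"
            )
        scale = float(rng.normal(spec.scale_radius_mean, spec.scale_radius_sd))
        if scale <= 0:
            raise RuntimeError("drew a non-positive scale radius; check the spec")
        noisy_ratio = ratio + spec.radial_noise * rng.normal(size=ratio.shape)
        if np.any(noisy_ratio <= 0):
            raise RuntimeError("radial noise made a radius non-positive")
        cloud0 = to_cartesian(theta, phi, scale * noisy_ratio)
        lm_points0, _ = _surface_points(coeffs, spec.order, lm_theta, lm_phi, scale)

        variants = [("right", 1.0)]
        if spec.mirror:
            variants.append(("left", -1.0))
        for side, xsign in variants:
            cloud = cloud0.copy()
            lm_points = lm_points0.copy()
            cloud[:, 0] *= xsign
            lm_points[:, 0] *= xsign
            if spec.misorient:
                rot = _random_rotation(rng)
                trans = rng.uniform(-50.0, 50.0, size=3)
            else:
                rot, trans = np.eye(3), np.zeros(3)
            bones.append(
                SyntheticBone(
                    cloud=cloud @ rot.T + trans,
                    landmarks=LandmarkSet.from_array(lm_points @ rot.T + trans),
                    coefficients=coeffs.copy(),
                    scale_radius=scale,
                    side=side,
                    rotation=rot,
                    translation=trans,
                )
            )
    return bones


@dataclass
class RasterizedBone:
    """A voxelized bone: the volume, a guaranteed-interior seed, and the
    physical position of the shape origin inside the voxel grid (mm)."""

    volume: Volume
    seed: SeedSpec
    origin_mm: np.ndarray


def rasterize(
    coefficients: np.ndarray,
    scale_radius: float,
    spacing: tuple[float, float, float],
    order: int | None = None,
    noise_sigma: float = 0.0,
    margin_mm: float = 3.0,
    blur_sigma_vox: float = 0.6,
    seed_tolerance: float = 0.04,
    seed: int | None = None,
) -> RasterizedBone:
    """Voxelize the analytic surface into a binary interior volume.

    Interior voxels (centre closer to the shape origin than the surface
    radius in that direction) get intensity 1, background 0; the grid covers
    the bounding sphere plus ``margin_mm`` of guaranteed background on every
    side.  The result is blurred with a small Gaussian and perturbed with
    additive noise, emulating partial-volume softening at the cortex.  The
    returned seed sits at the shape origin and is always interior.
    """
    coefficients = np.asarray(coefficients, dtype=float).reshape(-1)
    if order is None:
        order = int(round(np.sqrt(coefficients.size))) - 1
    if (order + 1) ** 2 != coefficients.size:
        raise ValueError("coefficient length must be (order+1)^2")
    xt, yt, zt = (float(s) for s in spacing)
    if min(xt, yt, zt) <= 0:
        raise ValueError("spacing components must be positive")

    # dense radius lookup R(theta, phi), wrapped in azimuth for interpolation
    th_grid = np.linspace(-np.pi, np.pi, 361)
    ph_grid = np.linspace(-np.pi / 2, np.pi / 2, 181)
    tt, pp = np.meshgrid(th_grid[:-1], ph_grid, indexing="ij")
    rr = scale_radius * (
        eval_basis(tt.ravel(), pp.ravel(), order) @ coefficients
    ).reshape(tt.shape)
    if np.any(rr <= 0):
        raise ValueError("surface is not star-shaped about the origin")
    rr_wrapped = np.vstack([rr, rr[:1]])  # theta = pi duplicates theta = -pi
    radius_of = RegularGridInterpolator(
        (th_grid, ph_grid), rr_wrapped, bounds_error=False, fill_value=None
    )

    r_max = float(rr.max())
    half = r_max + margin_mm
    n_cols = int(np.ceil(2 * half / xt)) + 1
    n_rows = int(np.ceil(2 * half / yt)) + 1
    n_slices = int(np.ceil(2 * half / zt)) + 1
    origin = np.array(
        [((n_cols - 1) // 2) * xt, ((n_rows - 1) // 2) * yt, ((n_slices - 1) // 2) * zt]
    )

    grid = np.zeros((n_rows, n_cols, n_slices))
    cols_x = np.arange(n_cols) * xt - origin[0]
    rows_y = np.arange(n_rows) * yt - origin[1]
    yy, xx = np.meshgrid(rows_y, cols_x, indexing="ij")
    for k in range(n_slices):
        dz = k * zt - origin[2]
        dist = np.sqrt(xx * xx + yy * yy + dz * dz)
        theta = np.arctan2(yy, xx)
        zratio = np.divide(dz, dist, out=np.zeros_like(dist), where=dist > 0)
        phi = np.arcsin(np.clip(zratio, -1, 1))
        surf = radius_of(np.stack([theta.ravel(), phi.ravel()], axis=1)).reshape(dist.shape)
        inside = dist <= surf
        if dist.flat[np.abs(dist).argmin()] == 0:  # voxel exactly at the origin
            inside[np.unravel_index(dist.argmin(), dist.shape)] = True
        grid[:, :, k] = inside.astype(float)

    n_interior = int(grid.sum())
    if n_interior < 8:
        raise ValueError("spacing too coarse for the shape (fewer than 8 interior voxels)")
    if blur_sigma_vox > 0:
        grid = gaussian_filter(grid, sigma=blur_sigma_vox)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        grid = grid + noise_sigma * rng.normal(size=grid.shape)

    seed_spec = SeedSpec(
        slice_index=(n_slices - 1) // 2,
        row=(n_rows - 1) // 2,
        col=(n_cols - 1) // 2,
        tolerance=seed_tolerance,
    )
    return RasterizedBone(
        volume=Volume(intensities=grid, spacing=(xt, yt, zt)),
        seed=seed_spec,
        origin_mm=origin,
    )
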