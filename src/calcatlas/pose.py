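"""Landmark-based canonical pose normalization.

Bones arrive in scanner coordinates with arbitrary position and orientation.
The canonical frame is defined by three of the six anatomical landmarks:

* E (most posterior point of the calcaneal tuberosity) moves to the origin;
* the plane pi_1 through C, D, E rotates into the plane z = 0, with its
  normal ``(C-E) x (D-E)`` mapped onto +z;
* C (highest point of the calcaneocuboid joint) rotates onto the +x axis.

The rotation is realised as two successive axis-angle rotations: ``r_alpha``
tilts the plane normal onto +z about the line of nodes (the intersection of
pi_1 with z = 0) by the dihedral angle alpha, and ``r_beta`` then rotates
about z by beta to bring C onto +x.  When the line of nodes happens to be
the x axis, ``r_alpha`` reduces to the elementary x rotation
``[[1,0,0],[0,cos a,-sin a],[0,sin a,cos a]]``.  Both operations are
isometric; no scaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkSet",
    "PoseTransform",
    "plane_through",
    "compute_pose",
    "apply_pose",
    "canonicalize",
    "DegenerateLandmarksError",
]

LANDMARK_NAMES = ("A", "B", "C", "D", "E", "F")


class DegenerateLandmarksError(ValueError):
    """C, D, E are (numerically) collinear; the pose frame is undefined."""


@dataclass
class LandmarkSet:
    """The six named anatomical landmarks A–F, physical coordinates in mm.

    A: highest point of the posterior articular facet; B: bottom of the
    posterior facet at the lateral surface; C/D: highest/lowest point of the
    calcaneocuboid joint; E: most posterior point of the calcaneal
    tuberosity; F: highest point on the superior edge of the tuberosity.
    G (midpoint of C and D) is derived.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} must be a finite 3-vector")
            setattr(self, name, p)

    @property
    def G(self) -> np.ndarray:
        """Midpoint of C and D (anterior end of the calcaneal axis)."""
        return 0.5 * (self.C + self.D)

    def as_array(self) -> np.ndarray:
        return np.stack([getattr(self, n) for n in LANDMARK_NAMES])

    @classmethod
    def from_array(cls, points: np.ndarray) -> "LandmarkSet":
        points = np.asarray(points, dtype=float)
        if points.shape != (6, 3):
            raise ValueError("expected a 6x3 landmark array (A..F)")
        return cls(*points)

    def transformed(self, pose: "PoseTransform") -> "LandmarkSet":
        return LandmarkSet.from_array(apply_pose(self.as_array(), pose))


@dataclass(frozen=True)
class PoseTransform:
    """Rigid motion p -> r_beta @ r_alpha @ (p + translation)."""

    translation: np.ndarray
    alpha: float
    beta: float
    r_alpha: np.ndarray
    r_beta: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        return self.r_beta @ self.r_alpha


def plane_through(C: np.ndarray, D: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, float]:
    """Plane through C, D, E as (unit normal, offset) with ``n . x = d``.

    The normal direction is ``(C - E) x (D - E)``, normalized.
    """
    C, D, E = (np.asarray(p, dtype=float).reshape(3) for p in (C, D, E))
    normal = np.cross(C - E, D - E)
    scale = max(np.linalg.norm(C - E), np.linalg.norm(D - E), 1e-300)
    norm = np.linalg.norm(normal)
    if norm <= 1e-12 * scale * scale:
        raise DegenerateLandmarksError("landmarks C, D, E are collinear")
    normal = normal / norm
    return normal, float(normal @ E)


def _rotation_to_z(normal: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimal rotation taking ``normal`` onto +z (Rodrigues about the line of nodes)."""
    nz = np.clip(normal[2], -1.0, 1.0)
    alpha = float(np.arccos(nz))
    axis = np.cross(normal, np.array([0.0, 0.0, 1.0]))
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-15:
        # normal already +z (alpha ~ 0) or exactly -z (flip about x)
        if nz > 0:
            return np.eye(3), 0.0
        return np.diag([1.0, -1.0, -1.0]), float(np.pi)
    axis = axis / axis_norm
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    r = np.eye(3) + np.sin(alpha) * k + (1.0 - np.cos(alpha)) * (k @ k)
    return r, alpha


def compute_pose(landmarks: LandmarkSet) -> PoseTransform:
    """Canonical pose from landmarks C, D, E.

    Applying the returned transform sends E to the origin, C onto the +x
    axis at distance ``|C - E|``, and D into the plane z = 0.  Sign
    conventions: the oriented normal ``(C-E) x (D-E)`` maps to +z and C to
    the positive x half-axis, which makes the canonical frame independent
    of the bone's incoming orientation (the cross product co-rotates with
    the landmarks).
    """
    normal, _ = plane_through(landmarks.C, landmarks.D, landmarks.E)
    r_alpha, alpha = _rotation_to_z(normal)
    c_rot = r_alpha @ (landmarks.C - landmarks.E)
    beta = float(np.arctan2(c_rot[1], c_rot[0]))
    cb, sb = np.cos(-beta), np.sin(-beta)
    r_beta = np.array([[cb, -sb, 0.0], [sb, cb, 0.0], [0.0, 0.0, 1.0]])
    return PoseTransform(
        translation=-landmarks.E.copy(),
        alpha=alpha,
        beta=beta,
        r_alpha=r_alpha,
        r_beta=r_beta,
    )


def apply_pose(points: np.ndarray, pose: PoseTransform) -> np.ndarray:
    """Apply the rigid motion to an N x 3 point array (or a single point)."""
    points = np.asarray(points, dtype=float)
    single = points.ndim == 1
    pts = np.atleast_2d(points)
    out = (pts + pose.translation) @ pose.rotation.T
    return out[0] if single else out


def canonicalize(points: np.ndarray, landmarks: LandmarkSet) -> tuple[np.ndarray, LandmarkSet, PoseTransform]:
    """Convenience wrapper: compute the pose and apply it to cloud + landmarks."""
    pose = compute_pose(landmarks)
    return apply_pose(points, pose), landmarks.transformed(pose), pose
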