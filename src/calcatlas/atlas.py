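"""Group-level coefficient atlases: summary statistics, quartile shapes,
and left/right symmetry correlation.

An atlas aggregates the per-bone SPHARM coefficient vectors of one group
(left, right or pooled) column-wise: mean, sample standard deviation and the
first/second/third quartiles (linear-interpolation convention, matching
``numpy.quantile``'s default).  Quartile shapes are surfaces reconstructed
from the per-coefficient Q1/median/Q3 vectors at the group-mean scale
radius.  Shape symmetry between sides is quantified by the squared Pearson
correlation of the two group-mean coefficient vectors, optionally after
removing the few largest-magnitude coefficients that dominate both sides
(by default ranked on the pooled left+right mean, absolute value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spharm import SpharmCoefficients, reconstruct

__all__ = ["AtlasModel", "summarize", "quartile_shapes", "symmetry_correlation"]


@dataclass
class AtlasModel:
    """Column-wise statistics of a (bones x Q) coefficient matrix."""

    group: str
    matrix: np.ndarray
    scale_radii: np.ndarray
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)
    q1: np.ndarray = field(init=False)
    median: np.ndarray = field(init=False)
    q3: np.ndarray = field(init=False)
    retained: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.scale_radii = np.asarray(self.scale_radii, dtype=float).reshape(-1)
        if self.matrix.ndim != 2:
            raise ValueError("coefficient matrix must be 2D (bones x Q)")
        if self.matrix.shape[0] < 2:
            raise ValueError("atlas statistics need at least 2 bones")
        if self.scale_radii.size != self.matrix.shape[0]:
            raise ValueError("one scale radius per bone required")
        self.mean = self.matrix.mean(axis=0)
        self.sd = self.matrix.std(axis=0, ddof=1)
        self.q1, self.median, self.q3 = np.quantile(
            self.matrix, [0.25, 0.5, 0.75], axis=0, method="linear"
        )

    @property
    def n_bones(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.matrix.shape[1]

    @property
    def order(self) -> int:
        L = int(round(np.sqrt(self.n_coefficients))) - 1
        if (L + 1) ** 2 != self.n_coefficients:
            raise ValueError("coefficient count is not a perfect square (L+1)^2")
        return L

    @property
    def mean_scale(self) -> float:
        return float(self.scale_radii.mean())


def summarize(matrix: np.ndarray, scale_radii: np.ndarray, group: str = "pooled") -> AtlasModel:
    """Build an :class:`AtlasModel` from per-bone coefficient rows."""
    return AtlasModel(group=group, matrix=matrix, scale_radii=scale_radii)


def quartile_shapes(
    atlas: AtlasModel, theta: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reconstruct the Q1, median and Q3 coefficient surfaces.

    Each quartile vector is treated as a coefficient set at the group-mean
    scale radius and evaluated at the given directions; returns three
    Cartesian point clouds.
    """
    shapes = []
    for vector in (atlas.q1, atlas.median, atlas.q3):
        coeffs = SpharmCoefficients(values=vector, scale=atlas.mean_scale, order=atlas.order)
        shapes.append(reconstruct(coeffs, theta, phi))
    return tuple(shapes)  # type: ignore[return-value]


def symmetry_correlation(
    left_mean: np.ndarray,
    right_mean: np.ndarray,
    exclude_top: int = 0,
    rank_by: str = "pooled_abs",
) -> tuple[float, float]:
    """Squared Pearson correlation of left/right mean coefficient vectors.

    ``exclude_top`` removes the coefficients of largest magnitude before
    correlating — by default ranked on the absolute pooled (left+right)/2
    mean; ``rank_by='pooled_value'`` ranks on the signed pooled mean
    instead.  Returns (r^2, two-sided p-value of the correlation).
    """
    left = np.asarray(left_mean, dtype=float).reshape(-1)
    right = np.asarray(right_mean, dtype=float).reshape(-1)
    if left.size != right.size:
        raise ValueError("left/right coefficient vectors must have equal length")
    if not 0 <= exclude_top < left.size:
        raise ValueError("exclude_top must be smaller than the vector length")
    if exclude_top:
        pooled = 0.5 * (left + right)
        if rank_by == "pooled_abs":
            score = np.abs(pooled)
        elif rank_by == "pooled_value":
            score = pooled
        else:
            raise ValueError(f"unknown rank_by: {rank_by!r}")
        drop = np.argsort(score)[-exclude_top:]
        keep = np.ones(left.size, dtype=bool)
        keep[drop] = False
        left, right = left[keep], right[keep]
    if left.size < 3 or np.ptp(left) == 0 or np.ptp(right) == 0:
        raise ValueError("correlation undefined: constant vector after exclusion")
    r, p = stats.pearsonr(left, right)
    return float(r * r), float(p)
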