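"""Seeded region growing and point-cloud assembly.

The calcaneal contour is extracted per sagittal slice by growing a
4-connected region from an operator-supplied seed pixel: a neighbouring
pixel joins the region when its intensity differs from the *running* region
mean by at most the tolerance ``tau``.  Contour pixels (region pixels with a
background 4-neighbour, the image border counting as background) from all
slices are scaled by the voxel spacing into one physical point cloud
``W = [x, y, z]`` in mm.

Coordinate convention (fixed, 0-based): x <-> column * xt, y <-> row * yt,
z <-> slice * zt.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SeedSpec", "region_grow", "mask_to_contour", "assemble_cloud"]

_NEIGHBOURS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass(frozen=True)
class SeedSpec:
    """Seed pixel for region growing: slice index, (row, col) and tolerance."""

    slice_index: int
    row: int
    col: int
    tolerance: float = 0.2

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("region-growing tolerance must be >= 0")


def region_grow(image: np.ndarray, seed: SeedSpec) -> np.ndarray:
    """Grow a 4-connected region from the seed under a running-mean criterion.

    A candidate pixel is admitted when ``|I[p] - mean(region)| <= tau`` with
    the mean taken over the region *at the moment of the test*.  Expansion is
    breadth-first in a fixed FIFO order (neighbours visited up, left, right,
    down), which makes the result deterministic even though the running mean
    drifts.  Returns a boolean mask containing the seed.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("region_grow expects a 2D slice")
    rows, cols = image.shape
    if not (0 <= seed.row < rows and 0 <= seed.col < cols):
        raise ValueError(f"seed ({seed.row}, {seed.col}) outside image {image.shape}")
    if seed.tolerance < 0:
        raise ValueError("tolerance must be >= 0")

    mask = np.zeros(image.shape, dtype=bool)
    mask[seed.row, seed.col] = True
    total = float(image[seed.row, seed.col])
    count = 1
    queue: deque[tuple[int, int]] = deque([(seed.row, seed.col)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in _NEIGHBOURS_4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc]:
                if abs(image[rr, cc] - total / count) <= seed.tolerance:
                    mask[rr, cc] = True
                    total += float(image[rr, cc])
                    count += 1
                    queue.append((rr, cc))
    return mask


def mask_to_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contour pixels of a binary mask, in row-major order.

    A mask pixel belongs to the contour when at least one of its 4-neighbours
    is background; pixels on the image border always qualify.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask_to_contour expects a 2D mask")
    if not mask.any():
        raise ValueError("cannot extract a contour from an empty mask")
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    rr, cc = np.nonzero(boundary)
    return list(zip(rr.tolist(), cc.tolist()))


def assemble_cloud(
    contours: Sequence[Iterable[tuple[int, int]]],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Concatenate per-slice contour pixels into a physical point cloud (mm).

    Pixel ``(row r, col c)`` in 0-based slice ``k`` maps to
    ``(c * xt, r * yt, k * zt)``.  Raises if every contour is empty.
    """
    xt, yt, zt = (float(s) for s in spacing)
    if min(xt, yt, zt) <= 0:
        raise ValueError("spacing components must be positive")
    points = [
        (c * xt, r * yt, k * zt)
        for k, contour in enumerate(contours)
        for r, c in contour
    ]
    if not points:
        raise ValueError("all contours are empty; nothing to assemble")
    return np.asarray(points, dtype=float)
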