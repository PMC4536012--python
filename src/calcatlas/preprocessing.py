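"""Volume decomposition and slice-level intensity conditioning.

A CT-like volume is decomposed into sagittal slices; each slice is min–max
normalized to [0, 1] in two steps (subtract the slice minimum, divide by the
resulting maximum) and then contrast-enhanced with a logistic (sigmoid)
mapping ``S(I) = 1 / (1 + exp(g (c - I)))`` with gain ``g`` and cut-off
``c``.  Normalization is per slice, not per volume, so each sagittal image
uses its full dynamic range before the contour-extraction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "SigmoidParams",
    "decompose_sagittal",
    "restack",
    "normalize_slice",
    "sigmoid_enhance",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the logistic contrast enhancement.

    ``gain`` controls the steepness, ``cutoff`` the intensity mapped to 0.5.
    Defaults follow the empirical settings used for calcaneal CT (0.4, 0.7).
    """

    gain: float = 0.4
    cutoff: float = 0.7

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain):
            raise ValueError("sigmoid gain must be finite")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("sigmoid cutoff must lie in [0, 1]")


@dataclass
class Volume:
    """A 3D intensity grid with physical voxel spacing.

    ``intensities`` has shape ``(m, n, o)``: image rows, image columns and
    slice count along the sagittal stacking axis.  ``spacing`` is
    ``(xt, yt, zt)`` in mm per voxel: ``xt``/``yt`` are the in-plane pixel
    spacings (columns/rows) and ``zt`` the slice thickness.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    frame_note: str = "FFS"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("volume must be a non-empty 3D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing components must be positive")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[2]


def decompose_sagittal(volume: Volume, axis: int = 2) -> list[np.ndarray]:
    """Split a volume into its stack of 2D sagittal slices.

    Slice ``k`` (0-based) is the k-th plane of the grid along ``axis``
    (default: the third array dimension).  Slices are returned as copies so
    in-place normalization cannot corrupt the source volume.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    grid = volume.intensities
    return [np.take(grid, k, axis=axis).copy() for k in range(grid.shape[axis])]


def restack(slices: list[np.ndarray], axis: int = 2) -> np.ndarray:
    """Inverse of :func:`decompose_sagittal` (stack slices back into a grid)."""
    if not slices:
        raise ValueError("cannot restack an empty slice list")
    return np.stack(slices, axis=axis)


def normalize_slice(pixels: np.ndarray) -> np.ndarray:
    """Two-step min–max normalization of one slice to [0, 1].

    Subtract the slice minimum, then divide by the maximum of the result.
    A constant slice (zero dynamic range) maps to all zeros: such slices
    contain no bone and the convention keeps the pipeline total.
    """
    pixels = np.asarray(pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("slice pixels must be finite")
    shifted = pixels - pixels.min()
    peak = shifted.max()
    if peak == 0.0:
        return np.zeros_like(shifted)
    return shifted / peak


def sigmoid_enhance(pixels: np.ndarray, params: SigmoidParams = SigmoidParams()) -> np.ndarray:
    """Logistic contrast enhancement ``1 / (1 + exp(g (c - I)))``, element-wise.

    Monotone non-decreasing in the input for positive gain, so pixel ordering
    (and the argmax location) is preserved; output lies in (0, 1).
    """
    pixels = np.asarray(pixels, dtype=float)
    return 1.0 / (1.0 + np.exp(params.gain * (params.cutoff - pixels)))
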