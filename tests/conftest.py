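import numpy as np
import pytest

from calcatlas import synthetic


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return synthetic._random_rotation(rng)


def random_blob_image(rng: np.random.Generator, size: int = 64) -> tuple[np.ndarray, tuple[int, int]]:
    """Binary-ish blob on noisy background with well-separated intensities.

    Foreground ~1 +/- 0.05, background ~0 +/- 0.05: the gap far exceeds the
    in-class spread, so running-mean and frozen-mean region growing agree.
    Returns the image and an interior seed pixel.
    """
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = rng.integers(20, size - 20, size=2)
    ry, rx = rng.integers(6, 14, size=2)
    blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    image = np.where(blob, 1.0, 0.0) + 0.05 * rng.uniform(-1, 1, size=(size, size))
    return image, (int(cy), int(cx))


@pytest.fixture(scope="session")
def base_bone() -> synthetic.SyntheticBone:
    """One noiseless, unrotated bone equal to the base reconstruction."""
    spec = synthetic.PopulationSpec(
        n_bones=1, seed=0, coefficient_sd=0.0, radial_noise=0.0,
        misorient=False, scale_radius_sd=0.0,
    )
    return synthetic.generate_population(spec)[0]


@pytest.fixture(scope="session")
def small_population() -> list[synthetic.SyntheticBone]:
    """A small misoriented cohort with mild variability, session-cached."""
    spec = synthetic.PopulationSpec(
        n_bones=6, seed=42, coefficient_sd=0.01, radial_noise=0.005, mirror=True
    )
    return synthetic.generate_population(spec)
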