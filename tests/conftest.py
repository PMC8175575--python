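import numpy as np
import pytest

from fibermorph import (
    LabelImage,
    SegmenterParams,
    SyntheticMuscleSpec,
    generate_muscle_section,
)

# mean fiber diameter (px) implied by the default lognormal(7.2, 0.35)
# at 1 um/px: d = sqrt(4 * exp(mu) / pi)
DEFAULT_DIAMETER_PX = float(np.sqrt(4 * np.exp(7.2) / np.pi))


@pytest.fixture(scope="session")
def uniform_section():
    """Noise-free, uniformly stained synthetic section (snap-frozen-like)."""
    spec = SyntheticMuscleSpec(n_fibers=150, seed=3)
    stack, labels = generate_muscle_section(spec)
    return spec, stack, labels


@pytest.fixture(scope="session")
def small_section():
    """Quick 40-fiber section for plumbing tests."""
    spec = SyntheticMuscleSpec(n_fibers=40, seed=1)
    stack, labels = generate_muscle_section(spec)
    return spec, stack, labels


@pytest.fixture(scope="session")
def default_params():
    return SegmenterParams(diameter_px=DEFAULT_DIAMETER_PX)


def permute_ids(img: LabelImage, seed: int = 0) -> LabelImage:
    """Randomly permute the positive label IDs of an image."""
    rng = np.random.default_rng(seed)
    ids = img.ids
    lut = np.zeros(int(img.pixels.max()) + 1, dtype=np.uint32)
    lut[ids] = rng.permutation(ids)
    return img.with_pixels(lut[img.pixels])
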