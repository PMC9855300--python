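import numpy as np
import pytest

from ovradiomics import (
    ImageVolume,
    PhantomConfig,
    SegmentationMask,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic phantom (image, mask) for extraction tests."""
    return generate_phantom(PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Unperturbed equal-axis ellipsoid phantom."""
    return generate_phantom(
        PhantomConfig(lobulation_amplitude=0.0, axis_ratios=(1, 1, 1), seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def noise_image(rng):
    return ImageVolume(rng.normal(100.0, 10.0, (16, 18, 20)), (2.5, 1.0, 1.0))
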