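import numpy as np
import pytest

from provseg.cohort import DegradationSpec, PhantomSpec, generate_phantom_pair
from provseg.network import ArchitectureConfig


@pytest.fixture(scope="session")
def tiny_phantom_spec():
    """A minimal valid phantom: fast to rasterize, still two curved tubes."""
    return PhantomSpec(
        grid_shape=(16, 20, 20),
        spacing_mm=(1.5, 1.5, 1.5),
        structure_length_mm=13.0,
        structure_radius_mm=2.5,
        curvature_mm=1.5,
        lateral_offset_mm=5.5,
        affine_jitter=(1.0, 1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_case(tiny_phantom_spec):
    return generate_phantom_pair(tiny_phantom_spec, "tiny", deg=DegradationSpec(seed=5))


@pytest.fixture(scope="session")
def tiny_arch():
    """Smallest useful network: 3 levels, 5-slice slab, 20x20 in-plane."""
    return ArchitectureConfig(
        n_levels=3, layers_per_dense_block=1, growth_rate=2,
        dropout_rate=0.1, in_plane_size=20, slab_in=5, sep_channels=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob_pair(seed: int, shape=(12, 12, 12), spacing=(1.5, 1.5, 1.5)):
    """Two seeded random smooth blobs as binary masks (both non-empty)."""
    from scipy import ndimage

    g = np.random.default_rng(seed)
    masks = []
    while len(masks) < 2:
        noise = ndimage.gaussian_filter(g.normal(size=shape), sigma=2.0)
        mask = noise > np.quantile(noise, 0.8)
        if mask.any():
            masks.append(mask)
    return masks[0], masks[1], spacing
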