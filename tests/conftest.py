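import numpy as np
import pytest

from meningrad import PhantomSpec, ROIMask, VoxelGrid, generate_phantom
from meningrad.grids import DiscretizedROI


@pytest.fixture
def textured_phantom():
    """A moderately textured non-cystic phantom (small, fast)."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        tumor_radii_mm=(10.0, 9.0, 8.0),
        texture_correlation_mm=1.5,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture
def constant_phantom():
    """Noiseless, field-free phantom: all masked voxels equal base intensity."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        tumor_radii_mm=(10.0, 9.0, 8.0),
        noise_sd=0.0,
        texture_correlation_mm=0.0,
        seed=0,
    )
    return generate_phantom(spec)


def disc_from_levels(levels: np.ndarray, ng: int) -> DiscretizedROI:
    """Wrap a raw level array as a DiscretizedROI for texture-matrix tests."""
    levels = np.asarray(levels, dtype=np.int32)
    return DiscretizedROI(
        levels=levels, ng=ng, bin_edges=np.arange(ng + 1, dtype=float)
    )


def grid_mask_from(values: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(values, spacing), ROIMask(mask, spacing)
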