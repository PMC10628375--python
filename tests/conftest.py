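import numpy as np
import pytest
from skimage.color import hed2rgb

from gridquant import CircularFOV, FieldCounts, inscribe_square_grid
from gridquant.synth import SyntheticFieldSpec, generate_field


def hed_image(h: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Render hematoxylin/eosin optical-density maps to an 8-bit RGB image."""
    hed = np.stack([h, e, np.zeros_like(h)], axis=-1)
    return (np.clip(hed2rgb(hed), 0, 1) * 255).round().astype(np.uint8)


@pytest.fixture(scope="session")
def single_cell_grid():
    """A 1-cell grid covering exactly the [0, 64) x [0, 64) pixel block."""
    side = 64.0
    fov = CircularFOV(32.0, 32.0, side * np.sqrt(2.0))
    return inscribe_square_grid(fov, n_per_side=1)


@pytest.fixture(scope="session")
def clear_cut_field():
    """One synthetic field with clear-cut cells and known per-cell labels."""
    spec = SyntheticFieldSpec(counts=FieldCounts(n_T=25, n_S=75, n_L=50), seed=7)
    image, labels, grid = generate_field(spec)
    return image, labels, grid
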