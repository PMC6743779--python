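import numpy as np
import pytest

from paircell.core import CellCrop, ChannelLayout
from paircell.simulate import SyntheticSpec, crops_from_images, generate_images


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_channel_layout():
    return ChannelLayout(("body", "protein"), (0,), (1,))


@pytest.fixture(scope="session")
def three_channel_layout():
    return ChannelLayout(("body", "nucleus", "protein"), (0, 1), (2,))


def make_dummy_crops(
    n_images: int, cells_per_image: int, size: int = 8, n_channels: int = 2, seed: int = 0
) -> list[CellCrop]:
    """Small random crops for contract tests that ignore pixel content."""
    rng = np.random.default_rng(seed)
    crops = []
    for g in range(n_images):
        for c in range(cells_per_image):
            crops.append(
                CellCrop(
                    pixels=rng.random((size, size, n_channels)).astype(np.float32),
                    image_id=f"img{g:03d}",
                    cell_id=f"cell{c:03d}",
                    center=(size // 2, size // 2),
                )
            )
    return crops


@pytest.fixture(scope="session")
def tiny_collection():
    """Two classes x three images, small fields: fast end-to-end material."""
    spec = SyntheticSpec(
        pattern_classes=("nuclear", "cytosolic"),
        images_per_class=3,
        cells_per_image=(4, 6),
        field_size=(128, 128),
        seed=7,
    )
    images = generate_images(spec)
    crops, labels = crops_from_images(images, crop_size=32)
    return spec, images, crops, labels
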