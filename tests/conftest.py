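import numpy as np
import pytest

from cicsquant import ChannelImage, FieldOfView, SyntheticSpec, generate_field
from cicsquant.segmentation import LabelMap


@pytest.fixture(scope="session")
def default_field():
    """One noiseless default field (10 BEC, 4 internalized, 3 attached, 5 free)."""
    spec = SyntheticSpec(seed=7)
    return generate_field(spec)


@pytest.fixture(scope="session")
def lysosome_field():
    spec = SyntheticSpec(
        n_internalized=5, n_attached=3, n_free=3,
        include_lysosome=True, lysosome_overlap_fraction=0.2, seed=21,
    )
    return generate_field(spec)


@pytest.fixture
def disk_image():
    """Two well-separated bright disks of radius 15 on zero background."""
    img = np.zeros((200, 200))
    yy, xx = np.mgrid[:200, :200]
    for cy, cx in [(50, 50), (140, 140)]:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 15**2] = 100.0
    return ChannelImage(img, role="bec")


def rasterize_ellipse(shape, center, a, b, orientation=0.0):
    from skimage.draw import ellipse

    mask = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(*center, a, b, shape=shape, rotation=orientation)
    mask[rr, cc] = True
    return mask


def label_map_from_masks(shape, masks):
    labels = np.zeros(shape, dtype=np.int32)
    for k, m in enumerate(masks, start=1):
        labels[m] = k
    return LabelMap(labels)
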