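import numpy as np
import pytest
from skimage import draw

from froa.contour import Silhouette, extract_contour
from froa.geometry import ViewingGeometry


def disc_mask(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


@pytest.fixture(scope="session")
def geometry() -> ViewingGeometry:
    return ViewingGeometry()


@pytest.fixture(scope="session")
def circle_sil() -> Silhouette:
    """Rasterised disc of radius 100 px."""
    return extract_contour(disc_mask((300, 300), (150, 150), 100))


@pytest.fixture(scope="session")
def dumbbell_mask() -> np.ndarray:
    """Two discs r=60 px with centres 100 px apart: one neck junction."""
    m = disc_mask((400, 400), (200, 150), 60)
    m |= disc_mask((400, 400), (200, 250), 60)
    return m


@pytest.fixture(scope="session")
def dumbbell_sil(dumbbell_mask) -> Silhouette:
    return extract_contour(dumbbell_mask)
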