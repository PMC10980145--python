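import math

import numpy as np
import pytest

from abquant.simulate import GroundTruthObject, rasterize_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ellipse_mask(
    shape,
    semi_major_px,
    semi_minor_px,
    orientation_rad=0.0,
    center=None,
    pixel_size_um=1.0,
):
    """Boolean mask of one rasterized ellipse (pixel-center-inside rule)."""
    if center is None:
        center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    obj = GroundTruthObject(
        object_id=1,
        center=center,
        semi_major_um=semi_major_px * pixel_size_um,
        semi_minor_um=semi_minor_px * pixel_size_um,
        orientation_rad=orientation_rad,
        true_class="plaque",
    )
    lab = rasterize_truth([obj], shape, pixel_size_um)
    return lab.labels == 1


def ellipse_perimeter_px(a, b):
    """Ramanujan approximation of an ellipse perimeter, pixels."""
    return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
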