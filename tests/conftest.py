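import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from synquant.image_io import CalibratedImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def disk_image():
    """Factory for single-channel calibrated images with filled disks."""

    def make(disks, shape=(64, 64), pixel_size=0.1, value=100.0, background=0.0):
        plane = np.full(shape, background, dtype=float)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        for cy, cx, r in disks:
            plane[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value
        return CalibratedImage(plane[np.newaxis], pixel_size, ["ch0"])

    return make


def random_label_map(rng, shape=(64, 64), n_blobs=6, r_range=(2, 6)):
    """Random non-overlapping-ish blob label map for overlap oracles."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(n_blobs):
        cy, cx = rng.integers(5, shape[0] - 5, 2)
        r = rng.integers(*r_range)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    return labels.astype(np.int32)
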