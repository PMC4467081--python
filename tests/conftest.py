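"""Shared fixtures: phantoms and their derived fields, computed once."""

import numpy as np
import pytest

from cellseg import preprocess, synthetic as syn
from cellseg.io_formats import Image2D


@pytest.fixture(scope="session")
def radial():
    """Radial bump phantom (bg 0.12 so 8-bit thresholds 45/65 apply),
    smoothed at sigma=3, with its gradient field."""
    img = syn.radial_phantom(background=0.12)
    sm = preprocess.smooth(img, 3.0)
    return img, sm, preprocess.gradient_field(sm)


@pytest.fixture(scope="session")
def radial_hi():
    """Radial bump phantom with the higher 0.2 background, smoothed."""
    img = syn.radial_phantom()
    sm = preprocess.smooth(img, 3.0)
    return img, sm, preprocess.gradient_field(sm)


@pytest.fixture(scope="session")
def single_scene():
    """One noisy single-cell scene with ground truth."""
    return syn.generate_scene(syn.single_cell_scene(seed=7))


@pytest.fixture()
def ramp_image():
    """I(x, y) = x / W on a 32x48 grid."""
    h, w = 32, 48
    data = np.tile(np.arange(w, dtype=float) / w, (h, 1))
    return Image2D(data)
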