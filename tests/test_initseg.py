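"""Thresholding and connected-component labeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellseg import initseg
from cellseg.exceptions import ParameterError
from cellseg.initseg import ThresholdSpec
from cellseg.io_formats import Image2D


def brute_force_otsu(data: np.ndarray) -> float:
    """Independent Otsu: scan 256 candidate thresholds, maximize
    between-class variance of the induced two-class split."""
    edges = np.linspace(data.min(), data.max(), 257)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = centers[0], -1.0
    flat = data.ravel()
    for t in centers:
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def test_mean_offset_on_constant_image():
    img = Image2D(np.full((10, 10), 0.3))
    t = initseg.compute_threshold(img, ThresholdSpec("mean_offset", offset=0.1))
    assert t == pytest.approx(0.4)


def test_otsu_on_bimodal_matches_brute_force():
    rng = np.random.default_rng(0)
    data = np.where(rng.uniform(size=(40, 40)) < 0.5, 0.2, 0.8)
    data += rng.normal(0, 0.01, data.shape)
    data = np.clip(data, 0, 1)
    img = Image2D(data)
    t = initseg.compute_threshold(img, ThresholdSpec("otsu_offset"))
    assert 0.2 < t < 0.8
    assert t == pytest.approx(brute_force_otsu(data), abs=0.02)


def test_absolute_threshold_is_passed_through():
    img = Image2D(np.random.default_rng(1).uniform(size=(10, 10)))
    spec = ThresholdSpec("absolute", absolute_value=45 / 255)
    assert initseg.compute_threshold(img, spec) == pytest.approx(0.17647, abs=1e-4)


def test_threshold_spec_validation():
    with pytest.raises(ParameterError):
        ThresholdSpec("absolute")                      # missing value
    with pytest.raises(ParameterError):
        ThresholdSpec("mean_offset", absolute_value=0.5)  # spurious value
    with pytest.raises(ParameterError):
        ThresholdSpec("median")                        # unknown method


def test_binarize_strict_inequality_and_bounds():
    img = Image2D(np.tile([0.4, 0.6], (8, 4)))
    assert initseg.binarize(img, 0.4).tolist()[0][:2] == [False, True]
    pos = Image2D(np.full((8, 8), 0.5))
    assert initseg.binarize(pos, 0.0).all()
    assert not initseg.binarize(pos, 1.0).any()


def test_diagonal_pixels_are_one_component():
    binary = np.zeros((8, 8), bool)
    binary[2, 2] = binary[3, 3] = True
    assert initseg.label_components(binary, 0).n_components == 1


def test_min_area_filter_against_flood_fill_oracle():
    """Components of area {10, 300, 500}; min_area 50 keeps two."""
    binary = np.zeros((60, 60), bool)
    binary[1:11, 1:2] = True          # area 10
    binary[20:35, 20:40] = True       # area 300
    binary[40:60, 10:35] = True       # area 500
    lm = initseg.label_components(binary, 50)
    assert lm.n_components == 2
    areas = lm.areas()
    assert list(areas[1:]) == [500, 300]  # descending-area label order


def test_empty_binary_grid():
    lm = initseg.label_components(np.zeros((8, 8), bool), 50)
    assert lm.n_components == 0 and not lm.labels.any()


def test_holes_are_filled():
    binary = np.zeros((20, 20), bool)
    binary[2:18, 2:18] = True
    binary[8:12, 8:12] = False  # hole
    lm = initseg.label_components(binary, 0)
    assert lm.areas()[1] == 16 * 16


def test_labeled_pixels_lie_above_threshold():
    """On hole-free foreground every labeled pixel exceeds the threshold
    (hole filling is the one documented exception, tested separately)."""
    data = np.full((32, 32), 0.2)
    data[5:15, 5:15] = 0.8
    data[20:30, 18:30] = 0.7
    img = Image2D(data)
    t = 0.5
    lm = initseg.label_components(initseg.binarize(img, t), 0)
    assert lm.n_components == 2
    assert np.all(img.data[lm.labels > 0] > t)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000),
       t1=st.floats(0.1, 0.5), dt=st.floats(0.01, 0.4))
def test_foreground_shrinks_with_threshold(seed, t1, dt):
    """For t1 < t2, foreground(t2) is a subset of foreground(t1)."""
    rng = np.random.default_rng(seed)
    img = Image2D(rng.uniform(size=(16, 16)))
    f1 = initseg.binarize(img, t1)
    f2 = initseg.binarize(img, min(t1 + dt, 1.0))
    assert np.all(f1[f2])  # f2 => f1


def test_out_of_range_threshold_warns_and_clips():
    img = Image2D(np.full((10, 10), 0.5))
    with pytest.warns(UserWarning, match="outside"):
        t = initseg.compute_threshold(img, ThresholdSpec("mean_offset", offset=0.9))
    assert t == 1.0
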