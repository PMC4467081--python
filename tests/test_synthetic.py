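"""Phantom generator: geometry, optics model, determinism, presets."""

import numpy as np
import pytest

from cellseg import synthetic as syn
from cellseg.exceptions import ParameterError
from cellseg.synthetic import (CellSpec, SceneSpec, SpeckleSpec, generate_scene,
                               height_map, intensity_from_phase, phase_shift,
                               render_intensity)


def one_cell_spec(**kw):
    cell = CellSpec(center_rc=(32.0, 32.0), semi_axes_px=(20.0, 15.0), **kw)
    return SceneSpec(shape=(64, 64), cells=[cell], noise_sigma=0.0)


def test_dome_apex_and_edge_values():
    spec = one_cell_spec(peak_height_um=4.0, nucleus_frac=0.0)
    h = height_map(spec)
    assert h[32, 32] == pytest.approx(4.0)
    # on the ellipse boundary (rho = 1) the height is zero
    assert h[32, 32 + 20] == 0.0
    assert h[32 + 15, 32] == 0.0


def test_nucleus_raises_apex_by_fraction():
    base = height_map(one_cell_spec(peak_height_um=4.0, nucleus_frac=0.0))
    with_nuc = height_map(one_cell_spec(peak_height_um=4.0, nucleus_frac=0.35))
    assert with_nuc[32, 32] == pytest.approx(base[32, 32] * 1.35)


def test_overlapping_domes_combine_by_max():
    c1 = CellSpec(center_rc=(32.0, 26.0), semi_axes_px=(14.0, 14.0),
                  peak_height_um=4.0)
    c2 = CellSpec(center_rc=(32.0, 40.0), semi_axes_px=(14.0, 14.0),
                  peak_height_um=3.0)
    spec = SceneSpec(shape=(64, 64), cells=[c1, c2], noise_sigma=0.0)
    h = height_map(spec)
    h1 = height_map(SceneSpec(shape=(64, 64), cells=[c1], noise_sigma=0.0))
    h2 = height_map(SceneSpec(shape=(64, 64), cells=[c2], noise_sigma=0.0))
    assert np.allclose(h, np.maximum(h1, h2))


def test_phase_shift_and_intensity_hand_computed():
    """n2-n1 = 0.03, h = 1 um, lambda = 0.55 um."""
    dphi = phase_shift(1.0, 1.335, 1.365, 0.55)
    assert dphi == pytest.approx(2 * np.pi * 0.03 / 0.55, abs=1e-12)
    assert dphi == pytest.approx(0.342719, abs=1e-5)
    assert intensity_from_phase(dphi) == pytest.approx(1.685439, abs=1e-5)


def test_zero_height_renders_flat_background():
    spec = SceneSpec(shape=(16, 16), cells=[], noise_sigma=0.0)
    img = render_intensity(np.zeros((16, 16)), spec)
    assert np.allclose(img.data, spec.background_level)


def test_doubling_height_doubles_contrast():
    spec = SceneSpec(shape=(16, 16), cells=[], noise_sigma=0.0)
    h1 = np.full((16, 16), 0.5)
    i1 = render_intensity(h1, spec).data - spec.background_level
    i2 = render_intensity(2 * h1, spec).data - spec.background_level
    assert np.allclose(i2, 2 * i1)


def test_intensity_linear_in_height_before_clipping():
    spec = one_cell_spec(peak_height_um=4.0)
    h = height_map(spec)
    img = render_intensity(h, spec)
    inside = h > 0
    corr = np.corrcoef(h[inside], img.data[inside] - spec.background_level)[0, 1]
    assert corr == pytest.approx(1.0, abs=1e-12)


def test_scene_deterministic_in_seed():
    a_img, a_truth = generate_scene(syn.field_scene(seed=9, shape=(256, 336),
                                                    n_cells=12))
    b_img, b_truth = generate_scene(syn.field_scene(seed=9, shape=(256, 336),
                                                    n_cells=12))
    assert np.array_equal(a_img.data, b_img.data)
    assert np.array_equal(a_truth.label_map.labels, b_truth.label_map.labels)


def test_field_preset_matches_imaging_regime():
    """120-150 cells per full frame and 12-20% coverage."""
    spec = syn.field_scene(seed=4)
    _, truth = generate_scene(spec)
    assert 120 <= len(spec.cells) <= 150
    assert 0.12 <= truth.coverage <= 0.20


def test_clump_preset_is_one_connected_component():
    from skimage.measure import label as sk_label

    _, truth = generate_scene(syn.clump_scene(4, seed=3))
    fg = truth.label_map.labels > 0
    assert truth.label_map.n_components == 4
    assert sk_label(fg, connectivity=2).max() == 1


def test_invalid_optics_rejected():
    with pytest.raises(ParameterError):
        SceneSpec(n1=1.4, n2=1.3)
    with pytest.raises(ParameterError):
        CellSpec(center_rc=(0, 0), semi_axes_px=(-1.0, 2.0))


def test_clipping_warning_on_overdriven_scale():
    spec = one_cell_spec(peak_height_um=6.0)
    spec.intensity_scale = 5.0
    with pytest.warns(UserWarning, match="clipped"):
        render_intensity(height_map(spec), spec)


def test_infeasible_packing_raises_generation_error():
    from cellseg.exceptions import GenerationError

    with pytest.raises(GenerationError):
        syn.field_scene(seed=0, shape=(96, 96), n_cells=50,
                        clustered_fraction=0.0)
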