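"""Contour extraction, the semi-implicit system, forces, and evolution."""

import numpy as np
import pytest

from cellseg import preprocess, snake
from cellseg.exceptions import ParameterError
from cellseg.io_formats import Image2D
from cellseg.preprocess import GradientField
from cellseg.snake import Contour, SnakeParams


def circle_contour(cx, cy, r, n=None):
    n = n or max(8, int(np.pi * r))
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]))


# ---------------------------------------------------------------- extraction

def test_square_boundary_extraction():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True  # 10x10 solid square
    c = snake.extract_initial_contour(mask)
    assert len(c) == pytest.approx(20, abs=2)       # perimeter 40 / spacing 2
    assert c.area() == pytest.approx(100, rel=0.05)
    assert c.signed_area() > 0                       # CCW


def test_disk_perimeter_matches_analytic():
    rr, cc = np.mgrid[0:50, 0:50]
    mask = (rr - 25) ** 2 + (cc - 25) ** 2 <= 15 ** 2
    c = snake.extract_initial_contour(mask)
    assert c.perimeter() == pytest.approx(2 * np.pi * 15, rel=0.03)


def test_thin_bar_yields_simple_polygon():
    mask = np.zeros((10, 30), bool)
    mask[4, 5:25] = True  # 1x20 bar
    c = snake.extract_initial_contour(mask)
    assert c.is_simple()
    assert len(c) >= 8


def test_empty_mask_rejected():
    with pytest.raises(ParameterError):
        snake.extract_initial_contour(np.zeros((10, 10), bool))


# ------------------------------------------------------------ linear system

def test_system_zero_gains_is_scaled_identity():
    m = snake.build_internal_system(10, SnakeParams(alpha=0.0, beta=0.0, gamma=1.5))
    assert np.allclose(m, 1.5 * np.eye(10))


def test_system_matches_stencil_assembly():
    """Assemble gamma*I - a*D2 + b*D4 from explicit periodic difference
    stencils and compare entrywise."""
    n, a, b, g = 8, 1.0, 0.3, 1.0

    def diff_matrix(stencil, offsets):
        m = np.zeros((n, n))
        for s, o in zip(stencil, offsets):
            for i in range(n):
                m[i, (i + o) % n] += s
        return m

    d2 = diff_matrix([1, -2, 1], [-1, 0, 1])
    d4 = diff_matrix([1, -4, 6, -4, 1], [-2, -1, 0, 1, 2])
    expected = g * np.eye(n) - a * d2 + b * d4
    got = snake.build_internal_system(n, SnakeParams(alpha=a, beta=b, gamma=g))
    assert np.allclose(got, expected)


def test_system_rows_sum_to_gamma_and_circulant():
    p = SnakeParams(alpha=0.07, beta=0.02, gamma=2.5)
    m = snake.build_internal_system(12, p)
    assert np.allclose(m.sum(axis=1), p.gamma)
    for k in range(1, 12):
        assert np.allclose(m[k], np.roll(m[0], k))
    assert np.all(np.linalg.eigvalsh(m) > 0)  # positive definite


# ------------------------------------------------------------------- forces

def test_bilinear_at_lattice_and_midpoint():
    gx = np.zeros((8, 8))
    gx[2, 3], gx[2, 4] = 0.2, 0.4
    f = GradientField(gx=gx, gy=np.zeros_like(gx), mag=np.abs(gx))
    pts = np.array([[3.0, 2.0], [3.5, 2.0]])  # (x, y)
    out = snake.external_force(f, pts, kappa=1.0)
    assert out[0, 0] == pytest.approx(-0.2)
    assert out[1, 0] == pytest.approx(-0.3)  # midpoint of 0.2 and 0.4


def test_force_points_outward_on_bright_bump():
    rr, cc = np.mgrid[0:41, 0:41]
    data = np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / (2 * 10.0 ** 2))
    field = preprocess.gradient_field(Image2D(data))
    c = circle_contour(20, 20, 8)
    forces = snake.external_force(field, c.points, kappa=2.0)
    radial = c.points - np.array([20.0, 20.0])
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    assert np.all(np.sum(forces * radial, axis=1) > 0)


# ---------------------------------------------------------------- evolution

def test_zero_field_zero_gains_is_fixed_point():
    img = Image2D(np.full((64, 64), 0.5))
    field = GradientField(gx=np.zeros((64, 64)), gy=np.zeros((64, 64)),
                          mag=np.zeros((64, 64)))
    # 38 equal chords: exactly uniform, so resampling is the identity
    c0 = circle_contour(32, 32, 12, n=38)
    p = SnakeParams(alpha=0.0, beta=0.0, max_iter=30, patience=5)
    cf, tr = snake.evolve(c0, img, field, p)
    assert tr.converged
    assert np.allclose(cf.points, c0.ensure_ccw().points, atol=1e-8)


def test_resampling_keeps_spacing_in_bounds(radial):
    _, sm, field = radial
    c0 = circle_contour(47.5, 47.5, 18)
    cf, _ = snake.evolve(c0, sm, field, SnakeParams())
    seg = np.hypot(*np.diff(np.vstack([cf.points, cf.points[:1]]), axis=0).T)
    assert seg.min() >= 0.5 and seg.max() <= 4.0


def test_trace_records_both_metrics(radial):
    _, sm, field = radial
    cf, tr = snake.evolve(circle_contour(47.5, 47.5, 18), sm, field, SnakeParams())
    assert len(tr.mean_intensity) == len(tr.mean_grad) == tr.n_iter + 1
    assert tr.converged


def test_collapsing_contour_raises_with_cell_id():
    from cellseg.exceptions import DegenerateContourError

    img = Image2D(np.full((32, 32), 0.5))
    field = GradientField(gx=np.zeros((32, 32)), gy=np.zeros((32, 32)),
                          mag=np.zeros((32, 32)))
    tiny = circle_contour(16, 16, 2.0, n=8)
    p = SnakeParams(alpha=5.0, beta=0.0, gamma=0.1, max_iter=200, patience=200)
    with pytest.raises(DegenerateContourError) as exc:
        snake.evolve(tiny, img, field, p, cell_id=7)
    assert exc.value.cell_id == 7
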