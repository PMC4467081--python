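"""Edge-based parametric active contour ("contour expansion").

The contour is a closed parametric curve v(s) = (x(s), y(s)) minimizing

    E = integral( 1/2 a |v_s|^2 + 1/2 b |v_ss|^2 + E_ext ) ds,

with tension gain a, rigidity gain b, and external energy proportional to
the image intensity along the curve. Stationarity gives the Euler-Lagrange
equation a v_ss - b v_ssss - grad E_ext = 0, which we integrate with the
classical semi-implicit scheme: the (linear) internal terms are treated
implicitly with viscosity gamma, the image force explicitly:

    (gamma I - a D2 + b D4) v_{t+1} = gamma v_t + F(v_t),

where D2/D4 are periodic second/fourth difference matrices. The system
matrix is circulant, so each step is a pair of FFT solves.

Seeded from a thresholded mask boundary (which sits inside the true cell
boundary for a bright convex cell), the down-slope image force F = -kappa
grad I pushes the curve outward until the internal forces balance the fading
edge gradient — hence "contour expansion". Convergence is monitored on the
mean light intensity sampled along the curve: while the curve descends the
cell's intensity hill the mean drops steadily, and it flattens once the
curve settles on the boundary. Iteration stops when the per-step change of
that mean stays below ``eps_converge`` for ``patience`` consecutive steps.
The mean gradient magnitude along the curve is recorded alongside it in the
trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.linalg import solve_circulant
from skimage.measure import find_contours

from .exceptions import DegenerateContourError, ParameterError
from .io_formats import Image2D
from .preprocess import GradientField

log = logging.getLogger(__name__)

_MIN_POINTS = 8
_MIN_AREA_PX = 4.0


@dataclass
class Contour:
    """Closed polygon of subpixel (x, y) vertices, counterclockwise.

    "Counterclockwise" means positive shoelace signed area in (x, y)
    coordinates (y increasing downward, as everywhere in this package).
    """

    points: np.ndarray  # (N, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ParameterError("Contour expects an (N, 2) array of (x, y) points")
        if len(self.points) < _MIN_POINTS:
            raise ParameterError(f"contour needs >= {_MIN_POINTS} points, got {len(self.points)}")

    def __len__(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid_rc(self) -> tuple[float, float]:
        """Polygon centroid as (row, col)."""
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return float(y.mean()), float(x.mean())
        cx = float(((x + xn) * cross).sum() / (6.0 * a))
        cy = float(((y + yn) * cross).sum() / (6.0 * a))
        return cy, cx

    def ensure_ccw(self) -> "Contour":
        if self.signed_area() < 0:
            return Contour(self.points[::-1].copy())
        return self

    def resample(self, spacing_px: float) -> "Contour":
        """Uniform arc-length resampling of the closed polyline."""
        pts = self.points
        closed = np.vstack([pts, pts[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        L = seg.sum()
        if L <= 0:
            raise DegenerateContourError("zero-length contour")
        n_new = max(_MIN_POINTS, int(round(L / spacing_px)))
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s_new = np.linspace(0.0, L, n_new, endpoint=False)
        x = np.interp(s_new, cum, closed[:, 0])
        y = np.interp(s_new, cum, closed[:, 1])
        return Contour(np.column_stack([x, y]))

    def is_simple(self) -> bool:
        """True if the polygon does not self-intersect (shapely check)."""
        from shapely.geometry import LinearRing

        try:
            return LinearRing(self.points).is_simple
        except Exception:
            return False


@dataclass
class SnakeParams:
    """Gains and iteration controls for contour expansion.

    alpha / beta: tension and rigidity gains (dimensionless; 0.01 each keeps
    the internal energy weak enough for the curve to reach the cell edge).
    gamma: viscosity / inverse time step of the semi-implicit scheme.
    kappa: image force weight multiplying -grad I. It must be large enough
    that the per-step drop of the convergence metric stays above
    eps_converge while the curve is still crossing the cell's rim —
    otherwise the termination rule cuts the expansion short on gently
    sloped boundaries. The default suits rim gradients of ~0.02-0.1
    intensity/px.
    eps_converge / patience: stop when the mean intensity along the curve
    changes by < eps_converge (normalized intensity units) for patience
    consecutive iterations.
    """

    alpha: float = 0.01
    beta: float = 0.01
    gamma: float = 1.0
    kappa: float = 6.0
    eps_converge: float = 0.002
    patience: int = 10
    max_iter: int = 500
    resample_spacing_px: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be >= 0")
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        if self.eps_converge <= 0:
            raise ParameterError("eps_converge must be > 0")
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if self.max_iter < self.patience:
            raise ParameterError("max_iter must be >= patience")
        if self.resample_spacing_px <= 0:
            raise ParameterError("resample_spacing_px must be > 0")


@dataclass
class EvolveTrace:
    """Per-iteration record: mean intensity (the convergence metric) and
    mean gradient magnitude along the contour."""

    mean_intensity: list[float] = field(default_factory=list)
    mean_grad: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def extract_initial_contour(mask: np.ndarray,
                            spacing_px: float = 2.0) -> Contour:
    """Trace the outer boundary of a (hole-filled) component as a CCW polygon.

    The mask is a full-frame boolean array containing one connected
    component. The 0.5-level contour of the padded mask is the outer
    boundary; it is resampled to uniform ``spacing_px`` arc length.
    Components touching the frame border are clipped to the border (the
    padding closes the curve there) and flagged in the log.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty mask has no boundary")
    if (mask[0, :].any() or mask[-1, :].any()
            or mask[:, 0].any() or mask[:, -1].any()):
        log.info("component touches the image border; contour clipped to border")
    padded = np.pad(mask.astype(np.float64), 1)
    contours = find_contours(padded, 0.5)
    if not contours:  # pragma: no cover - cannot happen for non-empty mask
        raise ParameterError("no boundary found")
    rc = max(contours, key=len)  # outer boundary is the longest
    # drop duplicated closing vertex; convert padded (row, col) -> (x, y)
    rc = rc[:-1] if np.allclose(rc[0], rc[-1]) else rc
    xy = np.column_stack([rc[:, 1] - 1.0, rc[:, 0] - 1.0])
    if len(xy) < _MIN_POINTS:  # tiny component: use its pixel corners
        raise ParameterError(f"component boundary has only {len(xy)} trace points")
    return Contour(xy).ensure_ccw().resample(spacing_px)


def _system_first_column(n: int, params: SnakeParams) -> np.ndarray:
    """First column of the circulant system matrix gamma*I - a*D2 + b*D4."""
    a, b, g = params.alpha, params.beta, params.gamma
    c = np.zeros(n)
    c[0] = g + 2.0 * a + 6.0 * b
    c[1] += -a - 4.0 * b
    c[-1] += -a - 4.0 * b
    c[2 % n] += b
    c[-2] += b
    return c


def build_internal_system(n: int, params: SnakeParams) -> np.ndarray:
    """Dense (n, n) semi-implicit system matrix gamma*I - (a*D2 - b*D4).

    D2 and D4 are the periodic second and fourth difference matrices
    (stencils [1, -2, 1] and [1, -4, 6, -4, 1]). The difference rows sum to
    zero, so every row of the returned matrix sums to gamma. With
    alpha = beta = 0 the system is gamma times the identity. The matrix is
    circulant and positive definite for any valid parameters.
    """
    if n < _MIN_POINTS:
        raise ParameterError(f"need n >= {_MIN_POINTS}, got {n}")
    c = _system_first_column(n, params)
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    return c[idx]


def _bilinear(grid: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a (H, W) grid at (x, y) points, clamped."""
    h, w = grid.shape
    x = np.clip(points[:, 0], 0.0, w - 1.0)
    y = np.clip(points[:, 1], 0.0, h - 1.0)
    return ndi.map_coordinates(grid, [y, x], order=1, mode="nearest")


def external_force(field_: GradientField, points: np.ndarray,
                   kappa: float = 6.0) -> np.ndarray:
    """Image force at each vertex: F = -kappa * grad I (bilinear sampled).

    The minus sign sends vertices down the intensity slope, i.e. outward on
    a bright convex cell body.
    """
    h, w = field_.shape
    pts = np.asarray(points, dtype=np.float64)
    out = (pts[:, 0] < 0) | (pts[:, 0] > w - 1) | (pts[:, 1] < 0) | (pts[:, 1] > h - 1)
    if out.any():
        log.debug("%d contour vertices outside the image; clamped", int(out.sum()))
    fx = -kappa * _bilinear(field_.gx, pts)
    fy = -kappa * _bilinear(field_.gy, pts)
    return np.column_stack([fx, fy])


def contour_mean_gradient(field_: GradientField, points: np.ndarray) -> float:
    """Mean |grad I| sampled along the contour."""
    return float(_bilinear(field_.mag, points).mean())


def contour_mean_intensity(image: Image2D, points: np.ndarray) -> float:
    """Mean intensity sampled along the contour (the convergence metric)."""
    return float(_bilinear(image.data, points).mean())


def evolve(initial: Contour, image: Image2D, field_: GradientField,
           params: SnakeParams, cell_id: int | None = None) -> tuple[Contour, EvolveTrace]:
    """Run contour expansion from ``initial`` to convergence.

    Each iteration: explicit image force, implicit internal solve (two
    circulant FFT solves), clamp to the image bounds, uniform arc-length
    resample, then update the convergence metric (mean intensity along the
    contour). Stops when the metric changes by < ``eps_converge`` for
    ``patience`` consecutive iterations, or at ``max_iter`` (trace flagged
    non-converged).
    """
    h, w = image.data.shape
    v = initial.resample(params.resample_spacing_px).ensure_ccw().points
    trace = EvolveTrace()
    m_prev = contour_mean_intensity(image, v)
    trace.mean_intensity.append(m_prev)
    trace.mean_grad.append(contour_mean_gradient(field_, v))
    streak = 0
    col = _system_first_column(len(v), params)

    for it in range(1, params.max_iter + 1):
        if len(v) != len(col):
            col = _system_first_column(len(v), params)
        f = external_force(field_, v, params.kappa)
        b = params.gamma * v + f
        v = np.column_stack([
            solve_circulant(col, b[:, 0]),
            solve_circulant(col, b[:, 1]),
        ])
        np.clip(v[:, 0], 0.0, w - 1.0, out=v[:, 0])
        np.clip(v[:, 1], 0.0, h - 1.0, out=v[:, 1])
        c = Contour(v) if len(v) >= _MIN_POINTS else None
        if c is None or c.area() < _MIN_AREA_PX:
            raise DegenerateContourError(
                f"contour collapsed at iteration {it}", cell_id=cell_id)
        c = c.resample(params.resample_spacing_px)
        if c.area() < _MIN_AREA_PX:
            raise DegenerateContourError(
                f"contour collapsed at iteration {it}", cell_id=cell_id)
        v = c.points

        m = contour_mean_intensity(image, v)
        trace.mean_intensity.append(m)
        trace.mean_grad.append(contour_mean_gradient(field_, v))
        streak = streak + 1 if abs(m - m_prev) < params.eps_converge else 0
        m_prev = m
        trace.n_iter = it
        if streak >= params.patience:
            trace.converged = True
            break
    if not trace.converged:
        log.warning("contour%s did not converge in %d iterations",
                    f" (cell {cell_id})" if cell_id is not None else "", params.max_iter)
    return Contour(v).ensure_ccw(), trace
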