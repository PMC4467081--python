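"""Physics-grounded negative-phase-contrast phantoms with ground truth.

A transparent cell of thickness h in medium of refractive index n1 (cell
index n2 > n1) retards the illumination by a phase shift

    dphi = 2 pi (n2 - n1) h / lambda,

and for small dphi the recorded negative-phase-contrast intensity is
approximately linear in it:

    I = |exp(j pi/2) + j dphi|^2 = |j (1 + dphi)|^2 ~ 1 + 2 dphi.

So a cell renders as a bright convex hill whose brightness tracks its height
profile — one apex above the nucleus. The generator builds per-cell dome
height maps (parabolic, spherical-cap, cosine or Gaussian profile on an
elliptical support), converts
them to intensity through the relation above, then adds the artifacts the
segmenter must survive: organelle speckles (small bright bumps inside
cells), cell-free debris blobs, and additive Gaussian noise. Every scene is
deterministic in its seed (numpy PCG64) and ships with a ground-truth label
map, true apex positions and per-cell pixel areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import GenerationError, ParameterError
from .initseg import LabelMap
from .io_formats import (DEFAULT_FRAME_SHAPE, DEFAULT_PIXEL_SIZE_X_UM,
                         DEFAULT_PIXEL_SIZE_Y_UM, Image2D)

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class CellSpec:
    """One elliptical dome-shaped cell body with a nucleus bump at its apex."""

    center_rc: tuple[float, float]
    semi_axes_px: tuple[float, float]  # (a, b): a along orientation
    orientation_rad: float = 0.0
    peak_height_um: float = 4.0
    profile: str = "parabolic"
    #: extra apex thickness from the nucleus, as a fraction of the body
    #: height; the nucleus makes the apex a sharp, unambiguous intensity peak
    nucleus_frac: float = 0.35
    nucleus_radius: float = 0.25  # nucleus extent, in normalized rho units

    def __post_init__(self) -> None:
        a, b = self.semi_axes_px
        if a <= 0 or b <= 0 or self.peak_height_um <= 0:
            raise ParameterError("cell geometry parameters must be positive")
        if self.profile not in {"parabolic", "cap", "cosine_dome", "gaussian_dome"}:
            raise ParameterError(f"unknown profile {self.profile!r}")


@dataclass
class SpeckleSpec:
    """Organelle pseudo-peak sources: small bright bumps inside cells."""

    count_per_cell: int = 0
    amplitude: float = 0.15
    radius_px: float = 2.0


@dataclass
class DebrisSpec:
    """Cell-free bright blobs (candidate over-detections)."""

    count: int = 0
    radius_px: float = 5.0
    level: float = 0.35


@dataclass
class SceneSpec:
    """Full description of a synthetic scene.

    Optics defaults: n2 - n1 = 0.03 (cytoplasm vs culture medium),
    lambda = 0.55 um (green illumination); intensity_scale maps the
    dimensionless contrast (I_raw - 1) onto the normalized [0, 1] camera
    scale so a 4 um apex sits near 0.6 above a 0.15 background.
    """

    shape: tuple[int, int] = DEFAULT_FRAME_SHAPE
    cells: list[CellSpec] = field(default_factory=list)
    n1: float = 1.335
    n2: float = 1.365
    lambda_um: float = 0.55
    background_level: float = 0.15
    intensity_scale: float = 0.165
    noise_sigma: float = 0.01
    speckles: SpeckleSpec = field(default_factory=SpeckleSpec)
    debris: DebrisSpec = field(default_factory=DebrisSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n2 <= self.n1:
            raise ParameterError("need n2 > n1: cells must be brighter than background")
        if self.lambda_um <= 0:
            raise ParameterError("lambda_um must be positive")
        if not (0.0 <= self.background_level <= 1.0):
            raise ParameterError("background_level must be in [0,1]")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["rng"] = "numpy.random.Generator(PCG64)"
        return d


@dataclass
class GroundTruth:
    """Truth labels (1..n in cell order), apex positions, per-cell areas."""

    label_map: LabelMap
    peaks: np.ndarray  # (n, 2) true apex (row, col)
    areas_px: np.ndarray

    @property
    def coverage(self) -> float:
        return float((self.label_map.labels > 0).mean())


def phase_shift(h_um: np.ndarray | float, n1: float, n2: float,
                lambda_um: float) -> np.ndarray | float:
    """dphi = 2 pi (n2 - n1) h / lambda."""
    return 2.0 * np.pi * (n2 - n1) * np.asarray(h_um, dtype=np.float64) / lambda_um


def intensity_from_phase(dphi: np.ndarray | float) -> np.ndarray | float:
    """Small-phase negative-contrast intensity: I ~ 1 + 2 dphi."""
    return 1.0 + 2.0 * np.asarray(dphi, dtype=np.float64)


def _dome(cell: CellSpec, shape: tuple[int, int]):
    """Height patch of one cell over its bounding box.

    Returns (rows slice, cols slice, heights); heights are zero outside the
    elliptical support. Body profiles, in normalized elliptical radius rho:

    * parabolic (default): H (1 - rho^2) — a spread adherent cell with a
      gently thinning periphery; the rim stays optically visible yet low
      thresholds still clip it, as real phase contrast cells behave;
    * cap: H sqrt(1 - rho^2) — a steep-edged spherical-cap body;
    * cosine_dome: H cos^2(pi rho / 2) — smooth apex, zero-slope
      (optically soft) rim;
    * gaussian_dome: Gaussian normalized so the edge is exactly zero.

    A Gaussian nucleus bump (``nucleus_frac`` extra thickness over a
    ``nucleus_radius`` core) rides on top of the body, making the apex a
    single sharp peak above the nucleus as in real adherent cells.
    """
    a, b = cell.semi_axes_px
    r0, c0 = cell.center_rc
    ext = max(a, b) + 1.0
    r_lo = max(0, int(np.floor(r0 - ext)))
    r_hi = min(shape[0], int(np.ceil(r0 + ext)) + 1)
    c_lo = max(0, int(np.floor(c0 - ext)))
    c_hi = min(shape[1], int(np.ceil(c0 + ext)) + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dr, dc = rr - r0, cc - c0
    ct, st = np.cos(cell.orientation_rad), np.sin(cell.orientation_rad)
    u = (dc * ct + dr * st) / a   # along-orientation (x-ish) axis
    w = (-dc * st + dr * ct) / b
    rho = np.sqrt(u * u + w * w)
    hmap = np.zeros_like(rho)
    inside = rho < 1.0
    ri = rho[inside]
    if cell.profile == "parabolic":
        body = 1.0 - ri ** 2
    elif cell.profile == "cap":
        body = np.sqrt(1.0 - ri ** 2)
    elif cell.profile == "cosine_dome":
        body = np.cos(np.pi * ri / 2.0) ** 2
    else:
        s = 0.4
        edge = np.exp(-1.0 / (2.0 * s * s))
        body = (np.exp(-ri ** 2 / (2.0 * s * s)) - edge) / (1.0 - edge)
    f = cell.nucleus_frac
    if f > 0:
        # nucleus thickness rides on top of the body; the rim is untouched
        body = body * (1.0 + f * np.exp(-ri ** 2 / (2.0 * cell.nucleus_radius ** 2)))
    hmap[inside] = cell.peak_height_um * body
    return slice(r_lo, r_hi), slice(c_lo, c_hi), hmap


def height_map(spec: SceneSpec, return_winner: bool = False):
    """Combined height grid (um); overlapping cells combine by pointwise max.

    With ``return_winner`` also returns an int grid of 1-based indices of the
    locally tallest cell (0 = no cell) — the ground-truth label map.
    """
    h = np.zeros(spec.shape, dtype=np.float64)
    winner = np.zeros(spec.shape, dtype=np.int32)
    for i, cell in enumerate(spec.cells, start=1):
        rs, cs, patch = _dome(cell, spec.shape)
        region = h[rs, cs]
        take = patch > region
        region[take] = patch[take]
        h[rs, cs] = region
        wr = winner[rs, cs]
        wr[take] = i
        winner[rs, cs] = wr
    if return_winner:
        return h, winner
    return h


def render_intensity(heights: np.ndarray, spec: SceneSpec,
                     add_noise: bool = True) -> Image2D:
    """Convert a height grid to a normalized phantom image.

    final = clip(background + scale * (I_raw - 1) + speckles + debris
                 + N(0, noise_sigma), 0, 1)
    with I_raw = 1 + 2 dphi from the phase model. Speckles are seeded
    uniformly inside each cell (elliptical radius < 0.6); debris blobs land
    on cell-free background.
    """
    heights = np.asarray(heights, dtype=np.float64)
    if (heights < 0).any():
        raise ParameterError("heights must be non-negative")
    rng = np.random.default_rng(spec.seed)
    dphi = phase_shift(heights, spec.n1, spec.n2, spec.lambda_um)
    img = spec.background_level + spec.intensity_scale * (intensity_from_phase(dphi) - 1.0)

    rr_full, cc_full = None, None
    if spec.speckles.count_per_cell > 0 and spec.cells:
        rad2 = 2.0 * spec.speckles.radius_px ** 2
        for cell in spec.cells:
            a, b = cell.semi_axes_px
            for _ in range(spec.speckles.count_per_cell):
                # uniform point at elliptical radius < 0.6 of this cell
                rho = 0.6 * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                u, w = rho * np.cos(ang) * a, rho * np.sin(ang) * b
                ct, st = np.cos(cell.orientation_rad), np.sin(cell.orientation_rad)
                pc = cell.center_rc[1] + u * ct - w * st
                pr = cell.center_rc[0] + u * st + w * ct
                img += _bump(spec.shape, pr, pc, spec.speckles.amplitude, rad2)
    if spec.debris.count > 0:
        rad2 = 2.0 * spec.debris.radius_px ** 2
        free = heights == 0
        margin = int(np.ceil(3 * spec.debris.radius_px))
        for _ in range(spec.debris.count):
            for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                pr = rng.uniform(margin, spec.shape[0] - margin)
                pc = rng.uniform(margin, spec.shape[1] - margin)
                if free[int(pr), int(pc)]:
                    break
            else:
                raise GenerationError("could not place debris on free background")
            img += _bump(spec.shape, pr, pc, spec.debris.level, rad2)
    if add_noise and spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    clipped = (img < 0) | (img > 1)
    if clipped.mean() > 0.10:
        warnings.warn(f"{clipped.mean():.0%} of pixels clipped; "
                      "check intensity_scale / background_level", stacklevel=2)
    return Image2D(np.clip(img, 0.0, 1.0))


def _bump(shape, pr, pc, amplitude, rad2):
    """Small Gaussian bump rendered over its local bounding box only."""
    out = np.zeros(shape)
    ext = int(np.ceil(3 * np.sqrt(rad2 / 2.0))) + 1
    r_lo, r_hi = max(0, int(pr) - ext), min(shape[0], int(pr) + ext + 1)
    c_lo, c_hi = max(0, int(pc) - ext), min(shape[1], int(pc) + ext + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    out[r_lo:r_hi, c_lo:c_hi] = amplitude * np.exp(
        -((rr - pr) ** 2 + (cc - pc) ** 2) / rad2)
    return out


def generate_scene(spec: SceneSpec) -> tuple[Image2D, GroundTruth]:
    """Realize a SceneSpec into an image plus ground truth (seed-deterministic)."""
    heights, winner = height_map(spec, return_winner=True)
    image = render_intensity(heights, spec)
    n = len(spec.cells)
    areas = np.bincount(winner.ravel(), minlength=n + 1)[1:].astype(np.float64)
    peaks = np.array([c.center_rc for c in spec.cells], dtype=np.float64).reshape(n, 2)
    truth = GroundTruth(LabelMap(winner, n), peaks, areas)
    return image, truth


# ---------------------------------------------------------------------------
# scene builders ("presets")
# ---------------------------------------------------------------------------

def radial_phantom(shape: tuple[int, int] = (96, 96),
                   plateau: float = 0.8, background: float = 0.2,
                   r_inner: float = 15.0, r_outer: float = 25.0) -> Image2D:
    """Analytic radially symmetric cell bump (no noise, no truth labels).

    Intensity = plateau inside ``r_inner``, cosine-squared falloff to
    ``background`` across [r_inner, r_outer]. This is the fixture for
    contour-expansion behavior studies (convergence traces, gain ordering,
    threshold robustness, circle-restricted energy checks).
    """
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(rr - (shape[0] - 1) / 2.0, cc - (shape[1] - 1) / 2.0)
    t = np.clip((r - r_inner) / (r_outer - r_inner), 0.0, 1.0)
    img = background + (plateau - background) * np.cos(np.pi * t / 2.0) ** 2
    return Image2D(img)


def single_cell_scene(seed: int = 0, shape=(128, 128), speckled: bool = False,
                      noise_sigma: float = 0.01) -> SceneSpec:
    """One mildly elliptical cell centered in a small frame."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(20.0, 26.0)
    b = a * rng.uniform(0.75, 1.0)
    spec = SceneSpec(
        shape=shape,
        cells=[CellSpec(center_rc=(shape[0] / 2.0, shape[1] / 2.0),
                        semi_axes_px=(a, b),
                        orientation_rad=rng.uniform(0, np.pi),
                        peak_height_um=rng.uniform(3.0, 5.0))],
        noise_sigma=noise_sigma,
        speckles=SpeckleSpec(count_per_cell=3, amplitude=0.18, radius_px=2.0)
        if speckled else SpeckleSpec(),
        seed=seed,
    )
    return spec


def clump_scene(k: int, seed: int = 0, shape=(192, 192),
                min_peak_separation_px: float = 15.0,
                noise_sigma: float = 0.01,
                irregular: bool = False) -> SceneSpec:
    """A single connected clump of k touching cells.

    Cells are added one at a time, each in contact with a randomly chosen
    placed cell (center distance ~75-85% of the sum of the semi-axes along
    the contact direction), keeping all apexes at least
    ``min_peak_separation_px`` apart. ``irregular`` draws elongated cells at
    random orientations, which makes the clump outline bumpy (the regime
    where shape-based watershed splitting fragments).
    """
    rng = np.random.default_rng(seed)
    cells: list[CellSpec] = []
    ctr = (shape[0] / 2.0, shape[1] / 2.0)

    def mk_cell(center):
        if irregular:
            a = rng.uniform(22.0, 30.0)
            b = a * rng.uniform(0.45, 0.65)
        else:
            a = rng.uniform(18.0, 24.0)
            b = a * rng.uniform(0.8, 1.0)
        return CellSpec(center_rc=center, semi_axes_px=(a, b),
                        orientation_rad=rng.uniform(0, np.pi),
                        peak_height_um=rng.uniform(3.0, 5.0))

    cells.append(mk_cell(ctr))
    for _ in range(1, k):
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            host = cells[rng.integers(len(cells))]
            ang = rng.uniform(0, 2 * np.pi)
            cand = mk_cell((0.0, 0.0))
            d = rng.uniform(0.75, 0.85) * (_radius_along(host, ang)
                                           + _radius_along(cand, ang + np.pi))
            center = (host.center_rc[0] + d * np.sin(ang),
                      host.center_rc[1] + d * np.cos(ang))
            cand = CellSpec(center_rc=center, semi_axes_px=cand.semi_axes_px,
                            orientation_rad=cand.orientation_rad,
                            peak_height_um=cand.peak_height_um)
            ok_sep = all(np.hypot(center[0] - c.center_rc[0],
                                  center[1] - c.center_rc[1])
                         >= min_peak_separation_px for c in cells)
            m = max(cand.semi_axes_px) + 2
            ok_frame = (m < center[0] < shape[0] - m and m < center[1] < shape[1] - m)
            if ok_sep and ok_frame:
                cells.append(cand)
                break
        else:
            raise GenerationError(f"could not place cell {len(cells)+1} of clump")
    return SceneSpec(shape=shape, cells=cells, noise_sigma=noise_sigma, seed=seed)


def _radius_along(cell: CellSpec, ang: float) -> float:
    """Ellipse support radius in direction ``ang`` (image angle, row/col)."""
    a, b = cell.semi_axes_px
    rel = ang - cell.orientation_rad
    return float(a * b / np.hypot(b * np.cos(rel), a * np.sin(rel)))


def field_scene(seed: int = 0, shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
                n_cells: int | None = None,
                clustered_fraction: float = 0.15,
                debris_count: int = 2,
                speckle_count_per_cell: int = 3,
                noise_sigma: float = 0.01) -> SceneSpec:
    """A full field of view in the imaging regime used for benchmarking:
    120-150 cells per 900 x 686 um frame at 12-20% area coverage, ~15% of
    cells in contact with a neighbour, a couple of debris blobs.
    """
    rng = np.random.default_rng(seed)
    if n_cells is None:
        n_cells = int(rng.integers(120, 151))
    cells: list[CellSpec] = []

    def mk_cell(center):
        a = rng.uniform(18.0, 27.0)
        b = a * rng.uniform(0.75, 1.0)
        return CellSpec(center_rc=center, semi_axes_px=(a, b),
                        orientation_rad=rng.uniform(0, np.pi),
                        peak_height_um=rng.uniform(2.0, 6.0))

    for i in range(n_cells):
        clustered = cells and rng.uniform() < clustered_fraction
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            cand = mk_cell((0.0, 0.0))
            m = max(cand.semi_axes_px) + 2
            if clustered:
                host = cells[rng.integers(len(cells))]
                ang = rng.uniform(0, 2 * np.pi)
                d = rng.uniform(0.75, 0.85) * (_radius_along(host, ang)
                                               + _radius_along(cand, ang + np.pi))
                center = (host.center_rc[0] + d * np.sin(ang),
                          host.center_rc[1] + d * np.cos(ang))
            else:
                center = (rng.uniform(m, shape[0] - m), rng.uniform(m, shape[1] - m))
            if not (m < center[0] < shape[0] - m and m < center[1] < shape[1] - m):
                continue
            sep_needed = 16.0 if clustered else None
            ok = True
            for c in cells:
                dist = np.hypot(center[0] - c.center_rc[0], center[1] - c.center_rc[1])
                if clustered:
                    if dist < sep_needed:
                        ok = False
                        break
                else:
                    # isolated cells must not touch anything
                    if dist < max(cand.semi_axes_px) + max(c.semi_axes_px) + 3:
                        ok = False
                        break
            if ok:
                cells.append(CellSpec(center_rc=center,
                                      semi_axes_px=cand.semi_axes_px,
                                      orientation_rad=cand.orientation_rad,
                                      peak_height_um=cand.peak_height_um))
                break
        else:
            raise GenerationError(
                f"could not place cell {i+1}/{n_cells}: coverage infeasible")
    return SceneSpec(shape=shape, cells=cells, noise_sigma=noise_sigma,
                     speckles=SpeckleSpec(count_per_cell=speckle_count_per_cell,
                                          amplitude=0.12, radius_px=2.0),
                     debris=DebrisSpec(count=debris_count, radius_px=5.0, level=0.35),
                     seed=seed)


def isolated_field_scene(seed: int = 0, n_cells: int = 50,
                         shape: tuple[int, int] = (640, 840)) -> SceneSpec:
    """Field of isolated (non-touching) cells for area-comparison studies."""
    return field_scene(seed=seed, shape=shape, n_cells=n_cells,
                       clustered_fraction=0.0, debris_count=0,
                       speckle_count_per_cell=0)


PRESETS = {
    "single": lambda seed: single_cell_scene(seed),
    "speckled": lambda seed: single_cell_scene(seed, speckled=True),
    "clump2": lambda seed: clump_scene(2, seed),
    "clump4": lambda seed: clump_scene(4, seed),
    "field130": lambda seed: field_scene(seed),
    "field50": lambda seed: isolated_field_scene(seed),
}
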