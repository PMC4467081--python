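"""Full segmentation pipeline.

smooth -> threshold -> binarize -> label components -> detect peaks ->
classify masks -> (single-peak: mask boundary; multi-peak: nearest-peak
partition) -> contour expansion per cell -> overlap resolution -> label map
+ per-cell records.

Everything is deterministic: components are processed in descending initial
mask area, peaks are ordered by scan position, rasterization overlaps are
resolved by nearest peak with ties to the lower cell id. Re-running with the
configuration echoed in a previous result reproduces the label map
bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from . import clumpsplit, initseg, preprocess, snake
from .exceptions import GeometryError, StageError
from .initseg import LabelMap, ThresholdSpec
from .io_formats import CellRecord, Image2D
from .snake import Contour, EvolveTrace, SnakeParams

log = logging.getLogger(__name__)


@dataclass
class SegmentConfig:
    """All pipeline knobs in one place (echoed into every result)."""

    sigma_px: float = preprocess.DEFAULT_SIGMA_PX
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    min_area_px: int = initseg.DEFAULT_MIN_AREA_PX
    snake: SnakeParams = field(default_factory=SnakeParams)
    #: frames whose intensity spread is below this are declared blank:
    #: mean- or Otsu-derived thresholds are meaningless at the noise floor
    min_contrast: float = 0.02
    keep_traces: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentConfig":
        d = dict(d)
        if isinstance(d.get("threshold"), dict):
            d["threshold"] = ThresholdSpec(**d["threshold"])
        if isinstance(d.get("snake"), dict):
            d["snake"] = SnakeParams(**d["snake"])
        return cls(**d)


@dataclass
class SegmentationResult:
    """Pipeline output: per-cell records, label map, config echo, traces."""

    cells: list[CellRecord]
    label_map: LabelMap
    config_echo: dict
    threshold_used: float = 0.0
    traces: dict[int, EvolveTrace] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def areas_um2(self) -> np.ndarray:
        return np.array([c.area_um2 for c in self.cells])


def compute_area(contour: Contour, pixel_size_x_um: float,
                 pixel_size_y_um: float) -> tuple[float, float]:
    """Polygon area by the shoelace formula, in px^2 and um^2.

    Clockwise input is auto-reoriented (logged); a self-intersecting polygon
    raises GeometryError.
    """
    if contour.signed_area() < 0:
        log.info("clockwise contour auto-reoriented to CCW")
        contour = contour.ensure_ccw()
    if not contour.is_simple():
        raise GeometryError("self-intersecting polygon has no well-defined area")
    a_px = contour.area()
    return a_px, a_px * pixel_size_x_um * pixel_size_y_um


def _repair(contour: Contour) -> Contour:
    """Make a near-simple polygon simple (largest piece of buffer(0))."""
    from shapely.geometry import Polygon

    poly = Polygon(contour.points)
    if poly.is_valid:
        return contour
    log.info("repairing self-intersecting contour")
    fixed = poly.buffer(0)
    if fixed.geom_type == "MultiPolygon":
        fixed = max(fixed.geoms, key=lambda g: g.area)
    xy = np.asarray(fixed.exterior.coords)[:-1]
    if len(xy) < 8:  # resample a tiny repaired ring up to the minimum count
        t = np.linspace(0, len(xy), 8, endpoint=False)
        xy = np.column_stack([np.interp(t, np.arange(len(xy) + 1),
                                        np.append(xy[:, k], xy[0, k])) for k in (0, 1)])
    return Contour(xy).ensure_ccw()


def _rasterize(contour: Contour, shape: tuple[int, int]):
    """Pixel centers inside the polygon (even-odd rule); returns (rows, cols)."""
    pts = contour.points
    c_lo = max(0, int(np.floor(pts[:, 0].min())))
    c_hi = min(shape[1] - 1, int(np.ceil(pts[:, 0].max())))
    r_lo = max(0, int(np.floor(pts[:, 1].min())))
    r_hi = min(shape[0] - 1, int(np.ceil(pts[:, 1].max())))
    if c_hi < c_lo or r_hi < r_lo:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    rr, cc = np.mgrid[r_lo:r_hi + 1, c_lo:c_hi + 1]
    inside = MplPath(pts, closed=True).contains_points(
        np.column_stack([cc.ravel(), rr.ravel()]))
    return rr.ravel()[inside], cc.ravel()[inside]


def segment(image: Image2D, config: SegmentConfig | None = None) -> SegmentationResult:
    """Segment all cells in a negative phase contrast frame."""
    config = config or SegmentConfig()
    shape = image.data.shape

    if float(image.data.std()) < config.min_contrast:
        log.info("frame contrast %.4f below floor %.3f: no foreground",
                 image.data.std(), config.min_contrast)
        return SegmentationResult([], LabelMap(np.zeros(shape, np.int32), 0),
                                  config.to_dict(), 0.0,
                                  {} if config.keep_traces else None)

    stage = "preprocess"
    try:
        smoothed = preprocess.smooth(image, config.sigma_px)
        field_ = preprocess.gradient_field(smoothed)
        stage = "threshold"
        thr = initseg.compute_threshold(smoothed, config.threshold)
        binary = initseg.binarize(smoothed, thr)
        stage = "label_components"
        labels = initseg.label_components(binary, config.min_area_px)
        stage = "detect_peaks"
        peaks = clumpsplit.detect_peaks(smoothed, labels, threshold=thr,
                                        smoothing_sigma_px=config.sigma_px)
        counts = clumpsplit.classify_masks(labels, peaks)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, None, e) from e

    if labels.n_components == 0:
        return SegmentationResult([], LabelMap(np.zeros(shape, np.int32), 0),
                                  config.to_dict(), thr, {} if config.keep_traces else None)

    # gather (initial contour, reference peak, from_clump) per prospective cell,
    # components in label order = descending initial mask area
    seeds: list[tuple[Contour, tuple[float, float], bool]] = []
    for k in range(1, labels.n_components + 1):
        mask = labels.mask(k)
        pk = peaks.in_component(k)
        try:
            if counts[k] <= 1:
                c0 = snake.extract_initial_contour(mask, config.snake.resample_spacing_px)
                ref = tuple(pk[0]) if len(pk) else _mask_centroid(mask)
                seeds.append((c0, ref, False))
            else:
                part = clumpsplit.partition_mask(mask, pk,
                                                config.snake.resample_spacing_px)
                for i, c0 in enumerate(part.subarea_contours):
                    seeds.append((c0, (float(pk[i, 0]), float(pk[i, 1])), True))
        except Exception as e:  # noqa: BLE001
            raise StageError("contour_init", k, e) from e

    traces: dict[int, EvolveTrace] = {}
    final: list[tuple[int, Contour, tuple[float, float], bool]] = []
    for cid, (c0, ref, from_clump) in enumerate(seeds, start=1):
        try:
            cf, tr = snake.evolve(c0, smoothed, field_, config.snake, cell_id=cid)
        except Exception as e:  # noqa: BLE001
            raise StageError("evolve", cid, e) from e
        cf = _repair(cf)
        final.append((cid, cf, ref, from_clump))
        if config.keep_traces:
            traces[cid] = tr

    # rasterize with nearest-peak overlap resolution (ties -> lower cell id)
    label_grid = np.zeros(shape, dtype=np.int32)
    dist_grid = np.full(shape, np.inf)
    for cid, cf, ref, _ in final:
        rr, cc = _rasterize(cf, shape)
        d = (rr - ref[0]) ** 2 + (cc - ref[1]) ** 2
        take = d < dist_grid[rr, cc]
        label_grid[rr[take], cc[take]] = cid
        dist_grid[rr[take], cc[take]] = d[take]

    cells = []
    for cid, cf, ref, from_clump in final:
        try:
            a_px, a_um2 = compute_area(cf, image.pixel_size_x_um, image.pixel_size_y_um)
        except GeometryError as e:
            raise StageError("compute_area", cid, e) from e
        cells.append(CellRecord(cell_id=cid, contour=cf, area_px=a_px,
                                area_um2=a_um2, centroid_rc=cf.centroid_rc(),
                                from_clump=from_clump,
                                peak_rc=(float(ref[0]), float(ref[1]))))
    return SegmentationResult(cells, LabelMap(label_grid, len(final)),
                              config.to_dict(), thr,
                              traces if config.keep_traces else None)


def _mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())
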