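"""Image input and result output.

Negative phase contrast frames arrive as single-channel 8- or 16-bit TIFF/PNG
images. They are normalized to floats in [0, 1] by the dtype maximum so that
all downstream thresholds and force gains live on one fixed intensity scale.
Results leave as a 16-bit label TIFF, a per-vertex contour CSV, a JSON file of
per-cell records (with the full configuration echoed for provenance), and an
RGB overlay PNG.

Coordinate convention, used everywhere in this package: rows index y
(downward), columns index x (rightward), both 0-based; contour vertices are
stored as (x_px, y_px) floats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from .exceptions import CapacityError, FormatError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints only
    from .pipeline import SegmentationResult
    from .snake import Contour

log = logging.getLogger(__name__)

#: Default physical pixel pitch: a 1344 x 1024 px sensor imaging a
#: 900 um x 686 um field of view (10x negative phase contrast objective).
DEFAULT_FRAME_SHAPE = (1024, 1344)  # (H, W)
DEFAULT_PIXEL_SIZE_X_UM = 900.0 / 1344.0
DEFAULT_PIXEL_SIZE_Y_UM = 686.0 / 1024.0


@dataclass
class Image2D:
    """A single-channel intensity grid with physical pixel sizes.

    ``data`` is float64 in [0, 1]; ``source_dtype`` records what the values
    were normalized from ("uint8", "uint16" or "float").
    """

    data: np.ndarray
    pixel_size_x_um: float = DEFAULT_PIXEL_SIZE_X_UM
    pixel_size_y_um: float = DEFAULT_PIXEL_SIZE_Y_UM
    source_dtype: str = "float"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError(f"Image2D requires a 2-D array, got ndim={self.data.ndim}")
        h, w = self.data.shape
        if h < 8 or w < 8:
            raise FormatError(f"image too small: {h}x{w}, need at least 8x8")
        if self.pixel_size_x_um <= 0 or self.pixel_size_y_um <= 0:
            raise FormatError("pixel sizes must be strictly positive")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < 0.0 or hi > 1.0:
            raise FormatError(f"intensities must lie in [0,1], got range [{lo}, {hi}]")

    @property
    def height_px(self) -> int:
        return self.data.shape[0]

    @property
    def width_px(self) -> int:
        return self.data.shape[1]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_x_um * self.pixel_size_y_um


@dataclass
class CellRecord:
    """Per-cell output: contour, areas, centroid and provenance flags."""

    cell_id: int
    contour: "Contour"
    area_px: float
    area_um2: float
    centroid_rc: tuple[float, float]
    from_clump: bool = False
    peak_rc: tuple[float, float] | None = None

    def to_jsonable(self) -> dict:
        d = {
            "cell_id": self.cell_id,
            "area_px": self.area_px,
            "area_um2": self.area_um2,
            "centroid_rc": list(self.centroid_rc),
            "from_clump": self.from_clump,
            "peak_rc": None if self.peak_rc is None else list(self.peak_rc),
            "n_vertices": len(self.contour.points),
        }
        return d


def read_image(path: str | Path,
               pixel_size_x_um: float | None = None,
               pixel_size_y_um: float | None = None) -> Image2D:
    """Read a grayscale TIFF/PNG and normalize intensities to [0, 1].

    Integer images are divided by their dtype maximum (255 or 65535); float
    images are clipped to [0, 1]. Multi-channel files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
    else:
        raw = np.asarray(PILImage.open(path))
    if raw.ndim == 3:
        raise FormatError(
            f"expected a single-channel image, got {raw.shape[-1]} channels in {path.name}")
    if raw.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {raw.ndim} in {path.name}")

    if raw.dtype == np.uint8:
        data = raw.astype(np.float64) / 255.0
        src = "uint8"
    elif raw.dtype == np.uint16:
        data = raw.astype(np.float64) / 65535.0
        src = "uint16"
    elif np.issubdtype(raw.dtype, np.integer):
        data = raw.astype(np.float64) / float(np.iinfo(raw.dtype).max)
        src = str(raw.dtype)
    else:
        data = np.clip(raw.astype(np.float64), 0.0, 1.0)
        src = "float"
    return Image2D(
        data,
        pixel_size_x_um=pixel_size_x_um or DEFAULT_PIXEL_SIZE_X_UM,
        pixel_size_y_um=pixel_size_y_um or DEFAULT_PIXEL_SIZE_Y_UM,
        source_dtype=src,
    )


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label grid as a 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 65535:
        raise CapacityError(f"{int(labels.max())} labels exceed the 16-bit TIFF capacity")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def _overlay_rgb(image: Image2D, result: "SegmentationResult") -> np.ndarray:
    """Burn contour outlines (red) into an RGB rendering of the input."""
    from skimage.draw import polygon_perimeter

    base = (np.clip(image.data, 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    for cell in result.cells:
        pts = cell.contour.points
        rr, cc = polygon_perimeter(pts[:, 1], pts[:, 0], shape=base.shape, clip=True)
        rgb[rr, cc] = (255, 40, 40)
    return rgb


def write_results(result: "SegmentationResult", out_dir: str | Path,
                  image: Image2D | None = None) -> dict[str, str]:
    """Write a segmentation result to ``out_dir``; returns a manifest.

    Files written: ``labels.tif`` (16-bit label map), ``contours.csv``
    (cell_id, vertex_index, x_px, y_px), ``cells.json`` (records + config
    echo), and ``overlay.png`` when the source image is provided.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    labels_path = out_dir / "labels.tif"
    write_label_map(result.label_map.labels, labels_path)
    manifest["label_map"] = str(labels_path)

    rows = []
    for cell in result.cells:
        for k, (x, y) in enumerate(cell.contour.points):
            rows.append((cell.cell_id, k, x, y))
    df = pd.DataFrame(rows, columns=["cell_id", "vertex_index", "x_px", "y_px"])
    csv_path = out_dir / "contours.csv"
    df.to_csv(csv_path, index=False)
    manifest["contours"] = str(csv_path)

    records = {
        "n_cells": len(result.cells),
        "config": result.config_echo,
        "cells": [c.to_jsonable() for c in result.cells],
    }
    json_path = out_dir / "cells.json"
    json_path.write_text(json.dumps(records, indent=2))
    manifest["cells"] = str(json_path)

    if image is not None:
        overlay_path = out_dir / "overlay.png"
        PILImage.fromarray(_overlay_rgb(image, result)).save(overlay_path)
        manifest["overlay"] = str(overlay_path)
    return manifest
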