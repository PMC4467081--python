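"""Global thresholding and connected-component labeling.

This is the "global" first pass: a single intensity threshold separates
bright cell bodies from the darker background, and 8-connected components of
the foreground become preliminary cell masks. The threshold can come from the
image mean plus an offset, from Otsu's between-class-variance criterion plus
an offset, or be given absolutely (figure-reproduction mode; absolute values
quoted on the 8-bit scale are converted by /255 before they reach here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .exceptions import ParameterError
from .io_formats import Image2D

log = logging.getLogger(__name__)

#: Components smaller than this are dropped as debris (~22 um^2 at the
#: default pixel pitch). Set to 0 to disable.
DEFAULT_MIN_AREA_PX = 50


@dataclass
class LabelMap:
    """Integer grid: 0 = background, k in 1..n_components = cell k."""

    labels: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, k: int) -> np.ndarray:
        """Boolean support of component ``k``."""
        return self.labels == k

    def areas(self) -> np.ndarray:
        """Pixel counts per label, index 0 = background."""
        return np.bincount(self.labels.ravel(), minlength=self.n_components + 1)


@dataclass
class ThresholdSpec:
    """Which thresholding rule to use.

    ``method`` is one of ``mean_offset``, ``otsu_offset``, ``absolute``;
    ``offset`` is in normalized intensity units ([0,1] scale);
    ``absolute_value`` is required (and only allowed) for ``absolute``.
    """

    method: str = "otsu_offset"
    offset: float = 0.0
    absolute_value: float | None = None

    def __post_init__(self) -> None:
        if self.method not in {"mean_offset", "otsu_offset", "absolute"}:
            raise ParameterError(f"unknown threshold method {self.method!r}")
        if self.method == "absolute":
            if self.absolute_value is None or not (0.0 <= self.absolute_value <= 1.0):
                raise ParameterError("absolute thresholding requires absolute_value in [0,1]")
        elif self.absolute_value is not None:
            raise ParameterError(f"absolute_value is only valid with method='absolute'")


def compute_threshold(image: Image2D, spec: ThresholdSpec) -> float:
    """Resolve a ThresholdSpec to a scalar threshold in [0, 1]."""
    if spec.method == "mean_offset":
        t = float(image.data.mean()) + spec.offset
    elif spec.method == "otsu_offset":
        t = float(threshold_otsu(image.data, nbins=256)) + spec.offset
    else:
        t = float(spec.absolute_value)
    if t < 0.0 or t > 1.0:
        warnings.warn(f"threshold {t:.4f} outside [0,1]; clipping", stacklevel=2)
        t = float(np.clip(t, 0.0, 1.0))
    return t


def binarize(image: Image2D, threshold: float) -> np.ndarray:
    """Foreground = pixels strictly above the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"threshold must be in [0,1], got {threshold}")
    return image.data > threshold


def label_components(binary: np.ndarray, min_area_px: int = DEFAULT_MIN_AREA_PX) -> LabelMap:
    """8-connected components of a binary mask, small ones dropped.

    Holes inside each component are filled (the expanding contour needs a
    single outer boundary per mask). Surviving components are relabeled
    1..n in order of decreasing area; ties broken by the first (row-major)
    pixel of the component.
    """
    if min_area_px < 0:
        raise ParameterError(f"min_area_px must be >= 0, got {min_area_px}")
    binary = np.asarray(binary, dtype=bool)
    filled = ndi.binary_fill_holes(binary)
    raw = sk_label(filled, connectivity=2)
    n_raw = int(raw.max())
    if n_raw == 0:
        return LabelMap(np.zeros_like(raw, dtype=np.int32), 0)

    areas = np.bincount(raw.ravel(), minlength=n_raw + 1)
    flat = raw.ravel()
    # first flat index of each label, for the deterministic tie rule
    first_idx = np.full(n_raw + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so that earlier indices overwrite later ones
    first_idx[flat[nz[::-1]]] = nz[::-1]

    keep = [k for k in range(1, n_raw + 1) if areas[k] >= max(min_area_px, 1)]
    keep.sort(key=lambda k: (-int(areas[k]), int(first_idx[k])))
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    return LabelMap(remap[raw], len(keep))
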