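"""Clustered-cell detection and splitting via intensity peaks.

A thresholded mask may cover several touching cells. Because each cell's
intensity is a convex hill with one apex over the nucleus, the number of
cells inside a mask equals the number of regional maxima of the *smoothed*
intensity there (smoothing first removes organelle pseudo-peaks). Masks with
two or more peaks are partitioned by assigning each pixel to its
Euclidean-nearest peak; each sub-area's boundary then seeds an independent
contour-expansion run. The expansion forgives small mistakes of the straight
nearest-peak division, because each curve settles on the true intensity edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

from .exceptions import ParameterError
from .initseg import LabelMap
from .io_formats import Image2D
from .preprocess import GradientField
from .snake import Contour, SnakeParams, evolve, extract_initial_contour

log = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Regional-maximum cell markers.

    ``rows``/``cols`` are subpixel plateau centroids in detection (row-major
    scan) order; ``intensities`` the plateau heights; ``labels`` the mask
    component each peak falls in (0 if somehow outside the foreground).
    """

    rows: np.ndarray
    cols: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    smoothing_sigma_px: float = 0.0

    def __len__(self) -> int:
        return len(self.rows)

    def in_component(self, k: int) -> np.ndarray:
        """(m, 2) array of (row, col) peaks inside component k, scan order."""
        sel = self.labels == k
        return np.column_stack([self.rows[sel], self.cols[sel]])


@dataclass
class ClumpPartition:
    """Nearest-peak division of one multi-peak mask component.

    ``assignment`` is a full-frame int array: -1 outside the component,
    0..k-1 = index of the owning peak inside it.
    """

    parent_label: int
    assignment: np.ndarray
    subarea_contours: list[Contour] = field(default_factory=list)


def detect_peaks(smoothed: Image2D, labels: LabelMap,
                 threshold: float = 0.0,
                 smoothing_sigma_px: float = 0.0) -> PeakSet:
    """8-connected regional maxima of the smoothed image, inside foreground.

    A plateau maximum contributes a single peak at its centroid. Maxima whose
    intensity is below the binarization threshold, or that fall outside the
    foreground, are discarded. Peaks are ordered by the row-major position of
    their plateau anchor, which makes all downstream tie-breaking
    deterministic.
    """
    data = smoothed.data
    maxmask = local_maxima(data, connectivity=2) & (labels.labels > 0)
    plateaus = sk_label(maxmask, connectivity=2)
    n = int(plateaus.max())
    if n == 0:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0),
                       np.empty(0, dtype=np.int32), smoothing_sigma_px)

    idx = np.arange(1, n + 1)
    coms = ndi.center_of_mass(maxmask, plateaus, idx)
    heights = ndi.maximum(data, plateaus, idx)
    # anchor pixel = first row-major pixel of each plateau, for ordering and
    # for reading the component label
    flat = plateaus.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")

    rows, cols, inten, labs = [], [], [], []
    w = labels.labels.shape[1]
    for j in order:
        if heights[j] <= threshold:
            continue
        r_anchor, c_anchor = divmod(int(first[j + 1]), w)
        rows.append(coms[j][0])
        cols.append(coms[j][1])
        inten.append(float(heights[j]))
        labs.append(int(labels.labels[r_anchor, c_anchor]))
    return PeakSet(np.asarray(rows), np.asarray(cols), np.asarray(inten),
                   np.asarray(labs, dtype=np.int32), smoothing_sigma_px)


def classify_masks(labels: LabelMap, peaks: PeakSet) -> dict[int, int]:
    """Map each component label to its peak count (clustered iff >= 2).

    A component without any detected peak is kept as a single cell (count
    coerced to 1) and flagged in the log.
    """
    counts = {k: 0 for k in range(1, labels.n_components + 1)}
    for lab in peaks.labels:
        if lab > 0:
            counts[int(lab)] += 1
    for k, c in counts.items():
        if c == 0:
            log.warning("component %d has no intensity peak; kept as one cell", k)
            counts[k] = 1
    return counts


def partition_mask(component: np.ndarray, peaks_in: np.ndarray,
                   spacing_px: float = 2.0) -> ClumpPartition:
    """Divide one mask component among its peaks by Euclidean distance.

    Every component pixel goes to the nearest peak (plain Euclidean pixel
    distance); ties go to the lowest peak index (peaks come in detection
    scan order). If a resulting sub-area is disconnected from its own peak —
    possible in bent clumps — only the connected part containing the peak is
    kept and the orphaned pixels are re-assigned by geodesic flooding within
    the mask; the event is logged.

    Sub-area boundaries are extracted and resampled exactly like single-cell
    initial contours.
    """
    component = np.asarray(component, dtype=bool)
    peaks_in = np.asarray(peaks_in, dtype=np.float64).reshape(-1, 2)
    k = len(peaks_in)
    if k < 1:
        raise ParameterError("partition_mask needs at least one peak")
    rr, cc = np.nonzero(component)
    d2 = ((rr[:, None] - peaks_in[None, :, 0]) ** 2
          + (cc[:, None] - peaks_in[None, :, 1]) ** 2)
    owner = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties

    assignment = np.full(component.shape, -1, dtype=np.int32)
    assignment[rr, cc] = owner

    # connectivity repair: each sub-area must contain its peak
    anchor_rc = np.column_stack([
        np.clip(np.rint(peaks_in[:, 0]).astype(int), 0, component.shape[0] - 1),
        np.clip(np.rint(peaks_in[:, 1]).astype(int), 0, component.shape[1] - 1),
    ])
    orphaned = np.zeros(component.shape, dtype=bool)
    for i in range(k):
        sub = assignment == i
        pieces = sk_label(sub, connectivity=2)
        if pieces.max() <= 1:
            continue
        own_piece = pieces[anchor_rc[i, 0], anchor_rc[i, 1]]
        if own_piece == 0:  # peak pixel itself grabbed by a tie: keep largest piece
            own_piece = int(np.argmax(np.bincount(pieces.ravel())[1:]) + 1)
        lost = sub & (pieces != own_piece)
        if lost.any():
            log.info("sub-area %d disconnected from its peak; re-assigning %d px "
                     "by geodesic distance", i, int(lost.sum()))
            assignment[lost] = -2
            orphaned |= lost
    if orphaned.any():
        markers = np.where(assignment >= 0, assignment + 1, 0)
        flooded = watershed(np.zeros_like(component, dtype=np.uint8),
                            markers=markers, mask=component)
        assignment[orphaned] = flooded[orphaned] - 1

    contours = []
    for i in range(k):
        contours.append(extract_initial_contour(assignment == i, spacing_px))
    return ClumpPartition(parent_label=0, assignment=assignment,
                          subarea_contours=contours)


def refine_clump(subcontours: list[Contour], image: Image2D,
                 field_: GradientField, params: SnakeParams,
                 cell_ids: list[int] | None = None):
    """Evolve each sub-area contour independently; returns (contours, traces).

    The expanded contours may overlap slightly; overlap is resolved later,
    at label-map rasterization, by the nearest-peak rule.
    """
    ids = cell_ids if cell_ids is not None else [None] * len(subcontours)
    out, traces = [], []
    for c, cid in zip(subcontours, ids):
        cf, tr = evolve(c, image, field_, params, cell_id=cid)
        out.append(cf)
        traces.append(tr)
    return out, traces
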