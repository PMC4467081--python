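"""Scoring a predicted segmentation against ground truth.

The error taxonomy distinguishes, per field of view:

* oversegmentation — more detected cells than truly present in an area
  (a true cell fragmented into several detections);
* undersegmentation — fewer detected than present (touching cells merged);
* over-detection — debris or artifacts detected as cells;
* overall rate — the sum of all three event counts over the true cell count.

The original judgment was visual; here it is made algorithmic: every
prediction is attributed to the truth object it overlaps most (and vice
versa), extra predictions per truth object count as oversegmentation events,
extra truth objects per prediction as undersegmentation events, predictions
overlapping no truth at all as over-detections, and mutually-best pairs with
IoU above a floor as matches. The counting is exactly self-dual: swapping
the roles of the two maps swaps the over- and under-segmentation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .initseg import LabelMap

DEFAULT_IOU_MIN = 0.5


@dataclass
class EvalReport:
    """Event counts and rates (each count / n_truth)."""

    n_truth: int
    n_pred: int
    n_matched: int
    n_overseg_events: int
    n_underseg_events: int
    n_overdetect: int

    def _rate(self, k: int) -> float:
        return k / self.n_truth if self.n_truth else 0.0

    @property
    def overseg_rate(self) -> float:
        return self._rate(self.n_overseg_events)

    @property
    def underseg_rate(self) -> float:
        return self._rate(self.n_underseg_events)

    @property
    def overdetect_rate(self) -> float:
        return self._rate(self.n_overdetect)

    @property
    def overall_rate(self) -> float:
        return self._rate(self.n_overseg_events + self.n_underseg_events
                          + self.n_overdetect)

    def to_jsonable(self) -> dict:
        return {
            "n_truth": self.n_truth, "n_pred": self.n_pred,
            "n_matched": self.n_matched,
            "n_overseg_events": self.n_overseg_events,
            "n_underseg_events": self.n_underseg_events,
            "n_overdetect": self.n_overdetect,
            "overseg_rate": self.overseg_rate,
            "underseg_rate": self.underseg_rate,
            "overdetect_rate": self.overdetect_rate,
            "overall_rate": self.overall_rate,
        }


def _contingency(a: np.ndarray, b: np.ndarray, na: int, nb: int):
    """Sparse overlap counts between two label grids (excluding 0-0)."""
    mask = (a > 0) | (b > 0)
    pair = a[mask].astype(np.int64) * (nb + 1) + b[mask].astype(np.int64)
    uniq, counts = np.unique(pair, return_counts=True)
    ta = (uniq // (nb + 1)).astype(int)
    tb = (uniq % (nb + 1)).astype(int)
    return ta, tb, counts


def match_and_count(pred: LabelMap, truth: LabelMap,
                    iou_min: float = DEFAULT_IOU_MIN) -> EvalReport:
    """Count match/over/under/over-detection events between two label maps."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if not (0.0 < iou_min < 1.0):
        raise ValueError(f"iou_min must be in (0,1), got {iou_min}")
    nt, np_ = truth.n_components, pred.n_components
    t_areas = truth.areas()
    p_areas = pred.areas()

    ti, pi, cnt = _contingency(truth.labels, pred.labels, nt, np_)

    # best-overlap attribution in both directions (ties -> lower id, via
    # iterating labels in increasing order with strict improvement)
    best_t_for_p = np.zeros(np_ + 1, dtype=int)   # 0 = none
    best_t_ov = np.zeros(np_ + 1, dtype=np.int64)
    best_p_for_t = np.zeros(nt + 1, dtype=int)
    best_p_ov = np.zeros(nt + 1, dtype=np.int64)
    iou_of = {}
    for t, p, c in sorted(zip(ti, pi, cnt)):
        if t == 0 or p == 0:
            continue
        if c > best_t_ov[p]:
            best_t_ov[p] = c
            best_t_for_p[p] = t
        if c > best_p_ov[t]:
            best_p_ov[t] = c
            best_p_for_t[t] = p
        iou_of[(t, p)] = c / (t_areas[t] + p_areas[p] - c)

    overseg = 0
    for t in range(1, nt + 1):
        claimants = int(np.sum(best_t_for_p[1:] == t))
        overseg += max(0, claimants - 1)
    underseg = 0
    for p in range(1, np_ + 1):
        claimed = int(np.sum(best_p_for_t[1:] == p))
        underseg += max(0, claimed - 1)
    overdetect = int(np.sum(best_t_ov[1:] == 0))

    matched = 0
    for t in range(1, nt + 1):
        p = best_p_for_t[t]
        if p and best_t_for_p[p] == t and iou_of.get((t, p), 0.0) >= iou_min:
            matched += 1

    return EvalReport(n_truth=nt, n_pred=np_, n_matched=matched,
                      n_overseg_events=overseg, n_underseg_events=underseg,
                      n_overdetect=overdetect)


def per_cell_iou(pred: LabelMap, truth: LabelMap) -> np.ndarray:
    """Best-candidate IoU for every truth cell (index k-1 = truth label k)."""
    nt, np_ = truth.n_components, pred.n_components
    t_areas = truth.areas()
    p_areas = pred.areas()
    ti, pi, cnt = _contingency(truth.labels, pred.labels, nt, np_)
    best = np.zeros(nt, dtype=np.float64)
    for t, p, c in zip(ti, pi, cnt):
        if t == 0 or p == 0:
            continue
        iou = c / (t_areas[t] + p_areas[p] - c)
        if iou > best[t - 1]:
            best[t - 1] = iou
    return best
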