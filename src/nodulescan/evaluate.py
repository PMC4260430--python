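"""Detection scoring: sensitivity and false positives per scan.

A truth nodule counts as detected when a retained candidate component
hits it under the configured rule — either the truth centroid falls
inside the component (default; the most permissive standard choice) or
the component/truth IoU reaches a threshold.  Every retained component
that overlaps no truth nodule at all counts as one false positive.
Detections of the same truth nodule on multiple slices of a scan are
merged by truth label before counting, so scan-level sensitivity never
double-counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import InvalidInputError
from .phantom import PhantomTruth

__all__ = [
    "SliceDetections",
    "DetectionResult",
    "match",
    "size_stratified_report",
    "vessel_fp_removal_fraction",
]


@dataclass
class SliceDetections:
    """Retained components of one slice: label image + retained label ids."""

    labels: np.ndarray
    retained: Sequence[int]


@dataclass
class NoduleRecord:
    scan_id: str
    slice_index: int
    truth_label: int
    diameter_mm: float
    attachment: str
    detected: bool


@dataclass
class DetectionResult:
    """Scan-level detection metrics.

    ``sensitivity`` is None when there are no truth nodules at all
    (undefined); false-positive counts remain valid.
    """

    per_scan: List[Tuple[str, int, int, int]]  # (scan_id, n_truth, n_detected, n_fp)
    nodules: List[NoduleRecord]
    sensitivity: Optional[float]
    fps_per_scan: float

    @property
    def n_truth(self) -> int:
        return sum(r[1] for r in self.per_scan)

    @property
    def n_detected(self) -> int:
        return sum(r[2] for r in self.per_scan)

    @property
    def n_fp(self) -> int:
        return sum(r[3] for r in self.per_scan)


def _component_hits(
    comp: np.ndarray,
    truth_mask: np.ndarray,
    hit_rule: str,
    iou_threshold: float,
) -> List[int]:
    """Truth labels hit by one component's pixel set."""
    if hit_rule not in ("centroid", "iou", "centroid_or_iou"):
        raise InvalidInputError(f"unknown hit rule {hit_rule!r}")
    hits = []
    for lab in np.unique(truth_mask[truth_mask > 0]):
        tm = truth_mask == lab
        hit = False
        if hit_rule in ("centroid", "centroid_or_iou"):
            rows, cols = np.nonzero(tm)
            cr, cc = int(round(rows.mean())), int(round(cols.mean()))
            hit = bool(comp[cr, cc])
        if not hit and hit_rule in ("iou", "centroid_or_iou"):
            inter = np.logical_and(comp, tm).sum()
            if inter:
                union = np.logical_or(comp, tm).sum()
                hit = inter / union >= iou_threshold
        if hit:
            hits.append(int(lab))
    return hits


def match(
    scans: Sequence[Tuple[str, Sequence[SliceDetections], Sequence[PhantomTruth]]],
    hit_rule: str = "centroid_or_iou",
    iou_threshold: float = 0.1,
) -> DetectionResult:
    """Match retained components against truth over a list of scans.

    Parameters
    ----------
    scans
        One entry per scan: (scan_id, per-slice detections, per-slice
        truths), slices aligned.
    hit_rule
        "centroid_or_iou" (default: truth centroid inside the component,
        or component/truth IoU >= ``iou_threshold`` — robust to an
        attached vessel carving the centroid pixel out of a component),
        "centroid", or "iou" alone.

    Notes
    -----
    A component overlapping any truth nodule pixel is not a false
    positive even if it fails the hit rule for every nodule — partial
    overlaps are neither credited nor penalised.
    """
    per_scan: List[Tuple[str, int, int, int]] = []
    records: List[NoduleRecord] = []
    for scan_id, dets, truths in scans:
        if len(dets) != len(truths):
            raise InvalidInputError(
                f"scan {scan_id!r}: {len(dets)} detection slices vs {len(truths)} truths"
            )
        detected: Dict[Tuple[int, int], bool] = {}
        n_fp = 0
        for si, (d, t) in enumerate(zip(dets, truths)):
            for k, spec_ in enumerate(t.specs, start=1):
                detected.setdefault((si, k), False)
            for lab in d.retained:
                comp = d.labels == lab
                hits = _component_hits(comp, t.nodule_mask, hit_rule, iou_threshold)
                if hits:
                    for h in hits:
                        detected[(si, h)] = True
                elif not np.logical_and(comp, t.nodule_mask > 0).any():
                    n_fp += 1
        n_truth = len(detected)
        n_det = sum(detected.values())
        per_scan.append((scan_id, n_truth, n_det, n_fp))
        for si, t in enumerate(truths):
            for k, spec_ in enumerate(t.specs, start=1):
                records.append(
                    NoduleRecord(
                        scan_id=scan_id,
                        slice_index=si,
                        truth_label=k,
                        diameter_mm=spec_.diameter_mm,
                        attachment=spec_.attachment,
                        detected=detected[(si, k)],
                    )
                )

    total_truth = sum(r[1] for r in per_scan)
    total_det = sum(r[2] for r in per_scan)
    total_fp = sum(r[3] for r in per_scan)
    sensitivity = (total_det / total_truth) if total_truth > 0 else None
    fps_per_scan = total_fp / len(per_scan) if per_scan else 0.0
    return DetectionResult(
        per_scan=per_scan,
        nodules=records,
        sensitivity=sensitivity,
        fps_per_scan=fps_per_scan,
    )


def size_stratified_report(
    result: DetectionResult,
    bins_mm: Sequence[float] = (3.0, 10.0, 20.0, 30.0),
) -> pd.DataFrame:
    """Sensitivity per diameter bin (default 3–10, 10–20, 20–30 mm).

    Empty bins carry NaN sensitivity (reported as n/a downstream).
    Detection improves with nodule size, so the per-bin sensitivities
    are expected to be non-decreasing on well-behaved suites.
    """
    rows = []
    edges = list(bins_mm)
    for lo, hi in zip(edges, edges[1:]):
        sel = [
            r for r in result.nodules
            if (lo <= r.diameter_mm < hi) or (hi == edges[-1] and r.diameter_mm == hi)
        ]
        n = len(sel)
        det = sum(r.detected for r in sel)
        rows.append(
            {
                "bin_mm": f"{lo:g}-{hi:g}",
                "n_truth": n,
                "n_detected": det,
                "sensitivity": det / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def plot_size_report(result: DetectionResult, path, bins_mm=(3.0, 10.0, 20.0, 30.0)):
    """Bar chart of actual vs detected nodule counts per size bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = size_stratified_report(result, bins_mm=bins_mm)
    x = np.arange(len(rep))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(x - 0.2, rep["n_truth"], width=0.4, label="actual")
    ax.bar(x + 0.2, rep["n_detected"], width=0.4, label="detected")
    ax.set_xticks(x, rep["bin_mm"])
    ax.set_xlabel("nodule size (mm)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vessel_fp_removal_fraction(
    scans: Sequence[Tuple[str, Sequence[SliceDetections], Sequence[PhantomTruth]]],
) -> Optional[float]:
    """Fraction of vessel-bearing slices with every pure-vessel FP removed.

    A slice counts as clean when no retained component overlaps the
    truth vessel mask unless that component also overlaps a truth
    nodule (a vessel-attached nodule legitimately drags vessel pixels
    into its component).  Returns None if no slice has vessels.
    """
    n_vessel_slices = 0
    n_clean = 0
    for _scan_id, dets, truths in scans:
        for d, t in zip(dets, truths):
            if not t.vessel_mask.any():
                continue
            n_vessel_slices += 1
            clean = True
            for lab in d.retained:
                comp = d.labels == lab
                if (comp & t.vessel_mask).any() and not (comp & (t.nodule_mask > 0)).any():
                    clean = False
                    break
            n_clean += clean
    if n_vessel_slices == 0:
        return None
    return n_clean / n_vessel_slices
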