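"""Segmentation evaluation metrics.

Implements the standard voxel-overlap and surface-distance quantities used to
score a predicted mask X against a reference standard GT:

* confusion counts TP / FP / FN / TN;
* DICE = 2TP / (2TP + FP + FN);
* JACCARD = TP / (TP + FP + FN);
* volumetric similarity VS = 1 - |FN - FP| / (2TP + FP + FN), which scores
  volume agreement irrespective of overlap position;
* the directed Hausdorff distance h(X, GT) = max_{x in X} min_{y in GT} |x - y|
  over boundary voxels in physical mm, and the symmetric
  HD(X, GT) = max(h(X, GT), h(GT, X));
* sensitivity (TPR) and specificity (TNR);
* Bland-Altman agreement of paired volume measurements;
* cohort-level report generation (mean ± sd and median (range) summaries).

Edge-case conventions, fixed here because real cohorts rarely hit them:
if both masks are empty the overlap scores are defined as 1 (perfect
agreement) and HD is undefined; if exactly one mask is empty DICE/JACCARD
are 0 and HD is undefined (an empty point set has no directed distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import LabelMask, require_same_grid

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "AgreementSummary",
    "confusion",
    "dice",
    "jaccard",
    "volumetric_similarity",
    "sensitivity_specificity",
    "boundary_points",
    "hausdorff",
    "bland_altman",
    "evaluate_pair",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel tallies between a predicted and a reference binary mask."""

    tp: int
    fp: int
    fn: int
    tn: int
    voxel_volume_mm3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def measured_volume_mm3(self) -> float:
        """Volume of the prediction (TP + FP) in mm³."""
        return (self.tp + self.fp) * self.voxel_volume_mm3

    @property
    def reference_volume_mm3(self) -> float:
        return (self.tp + self.fn) * self.voxel_volume_mm3


def confusion(pred: LabelMask, ref: LabelMask, label: int = 1) -> ConfusionCounts:
    """Exact TP/FP/FN/TN tallies for one label (one-vs-rest)."""
    require_same_grid(pred, ref)
    p = pred.binary(label)
    r = ref.binary(label)
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn, pred.voxel_volume_mm3)


def dice(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:  # both masks empty: perfect agreement by convention
        return 1.0
    return 2 * c.tp / den


def jaccard(c: ConfusionCounts) -> float:
    den = c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return c.tp / den


def volumetric_similarity(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 1.0 - abs(c.fn - c.fp) / den


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(TPR, TNR); NaN where the defining denominator is zero."""
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    return tpr, tnr


# 6-connectivity structuring element for boundary extraction
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical (mm) coordinates of boundary voxels of a binary mask.

    A boundary voxel is a foreground voxel with at least one 6-neighbour in
    the background (erosion difference); voxel centers are scaled by spacing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    surf = mask & ~interior
    idx = np.argwhere(surf).astype(np.float64)
    return idx * np.asarray(spacing, dtype=np.float64)


def _directed_hd(a: np.ndarray, b_tree: cKDTree) -> float:
    d, _ = b_tree.query(a, k=1)
    return float(np.max(d))


def hausdorff(
    pred: np.ndarray, ref: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> tuple[float, float, float]:
    """Directed and symmetric Hausdorff distances in mm.

    Parameters may be binary masks (boundaries are extracted) or (n, 3)
    point arrays already in voxel index units (then scaled by spacing).

    Returns ``(h(X, GT), h(GT, X), HD)`` where HD is the max of the two
    directed distances.  Raises on an empty input (undefined).
    """
    spacing = np.asarray(spacing, dtype=np.float64)

    def as_points(m: np.ndarray) -> np.ndarray:
        m = np.asarray(m)
        if m.ndim == 2 and m.shape[1] == 3:
            if len(m) == 0:
                raise ValueError("empty point set: Hausdorff distance undefined")
            return m.astype(np.float64) * spacing
        return boundary_points(m, spacing)

    x = as_points(pred)
    gt = as_points(ref)
    h_x_gt = _directed_hd(x, cKDTree(gt))
    h_gt_x = _directed_hd(gt, cKDTree(x))
    return h_x_gt, h_gt_x, max(h_x_gt, h_gt_x)


@dataclass
class MetricReport:
    """All per-case metrics for one label, ready for tabulation."""

    dice: float
    jaccard: float
    vs: float
    hd_mm: float  # NaN when undefined (an empty mask)
    tpr: float
    tnr: float
    measured_volume_mm3: float
    reference_volume_mm3: float
    counts: ConfusionCounts

    def as_row(self) -> dict[str, float]:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "vs": self.vs,
            "hd_mm": self.hd_mm,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "measured_volume_mm3": self.measured_volume_mm3,
            "reference_volume_mm3": self.reference_volume_mm3,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }


def evaluate_pair(pred: LabelMask, ref: LabelMask, label: int = 1) -> MetricReport:
    c = confusion(pred, ref, label)
    p = pred.binary(label)
    r = ref.binary(label)
    if p.any() and r.any():
        _, _, hd = hausdorff(p, r, pred.spacing)
    else:
        hd = math.nan
    tpr, tnr = sensitivity_specificity(c)
    return MetricReport(
        dice=dice(c),
        jaccard=jaccard(c),
        vs=volumetric_similarity(c),
        hd_mm=hd,
        tpr=tpr,
        tnr=tnr,
        measured_volume_mm3=c.measured_volume_mm3,
        reference_volume_mm3=c.reference_volume_mm3,
        counts=c,
    )


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman agreement of paired measurements (a - b differences)."""

    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    differences: tuple[float, ...] = field(default=(), repr=False)
    means: tuple[float, ...] = field(default=(), repr=False)


def bland_altman(measured, reference) -> AgreementSummary:
    """Bias and 1.96-sd limits of agreement for paired measurements.

    Differences are measured - reference; sd is the sample standard
    deviation (n - 1).  The per-pair (mean, difference) scatter data are
    carried on the result for plotting.
    """
    a = np.asarray(measured, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("measured and reference must be 1D arrays of equal length")
    if len(a) < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.std(a) > 0 and np.std(b) > 0:
        r = float(np.corrcoef(a, b)[0, 1])
    else:
        r = math.nan
    return AgreementSummary(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=r,
        differences=tuple(d),
        means=tuple((a + b) / 2.0),
    )


def _union_mask(mask: LabelMask, labels) -> LabelMask:
    return LabelMask(np.isin(mask.data, list(labels)).astype(np.int16), mask.spacing)


def evaluate_cohort(
    preds: list[LabelMask],
    refs: list[LabelMask],
    labels: list[int],
    label_names: dict[int, str] | None = None,
    union_name: str = "whole",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case metric table and cohort summary over matched mask lists.

    Each label is scored one-vs-rest; an additional row scores the union of
    all labels (e.g. the whole aneurysm = thrombus OR stent+lumen).

    Returns
    -------
    per_case:
        one row per (case, region) with all metrics and raw counts.
    summary:
        per region: mean ± sd and median (range) for each metric, mirroring
        the two reporting conventions used for cohort tables.
    """
    if len(preds) != len(refs):
        raise ValueError(f"{len(preds)} predictions vs {len(refs)} references")
    label_names = label_names or {}
    rows = []
    for i, (p, r) in enumerate(zip(preds, refs)):
        for lab in labels:
            rep = evaluate_pair(p, r, lab)
            rows.append({"case": i, "region": label_names.get(lab, str(lab)), **rep.as_row()})
        if len(labels) > 1:
            rep = evaluate_pair(_union_mask(p, labels), _union_mask(r, labels), 1)
            rows.append({"case": i, "region": union_name, **rep.as_row()})
    per_case = pd.DataFrame(rows)

    metric_cols = ["dice", "jaccard", "vs", "hd_mm", "tpr", "tnr", "measured_volume_mm3"]
    pieces = []
    for region, grp in per_case.groupby("region", sort=False):
        rec: dict[str, object] = {"region": region}
        for col in metric_cols:
            v = grp[col].to_numpy(dtype=float)
            rec[f"{col}_mean"] = float(np.nanmean(v))
            rec[f"{col}_sd"] = float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0
            rec[f"{col}_median"] = float(np.nanmedian(v))
            rec[f"{col}_min"] = float(np.nanmin(v))
            rec[f"{col}_max"] = float(np.nanmax(v))
        pieces.append(rec)
    summary = pd.DataFrame(pieces)
    return per_case, summary
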