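"""Confusion-matrix cardinalities and the six volumetric overlap metrics.

Ground truth and test segmentations are compared voxelwise inside the
smallest axis-aligned box enclosing both masks.  Restricting to that box
leaves TP, FP and FN untouched (every positive voxel of either mask lies
inside it) but deflates the otherwise whole-CT true-negative count, which
would drive TNR and RI to ~1 regardless of contour quality.

Metrics: DSC = 2TP/(2TP+FP+FN), JAC = TP/(TP+FP+FN) = DSC/(2-DSC),
TPR = TP/(TP+FN) (sensitivity/recall), TNR = TN/(TN+FP) (specificity),
PPV = TP/(TP+FP) (precision), RI = (TP+TN)/(TP+TN+FP+FN).  Any 0/0 ratio
is reported as NaN rather than forced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import OVERLAP_METRIC_NAMES
from .volumes import BinaryMask, BoxRegion, GeometryError

__all__ = [
    "DegenerateInputError",
    "ConfusionCounts",
    "OverlapMetrics",
    "bounding_box_union",
    "confusion_counts",
    "overlap_metrics",
    "compare_overlap",
]


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. both masks empty)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel cardinalities m_ij evaluated inside ``region``.

    TP = m11, FP = m10, FN = m01, TN = m00; their sum is the region's voxel
    count.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    region: BoxRegion

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        total = self.tp + self.fp + self.fn + self.tn
        if total != self.region.n_voxels:
            raise ValueError(
                f"counts sum to {total}, region holds {self.region.n_voxels} voxels"
            )


@dataclass(frozen=True)
class OverlapMetrics:
    dsc: float
    jac: float
    tpr: float
    tnr: float
    ppv: float
    ri: float

    def as_dict(self) -> dict[str, float]:
        vals = {
            "DSC": self.dsc,
            "JAC": self.jac,
            "TPR": self.tpr,
            "TNR": self.tnr,
            "RI": self.ri,
            "PPV": self.ppv,
        }
        return {k: vals[k] for k in OVERLAP_METRIC_NAMES}


def _check_same_grid(gt: BinaryMask, test: BinaryMask) -> None:
    if not gt.same_grid(test):
        raise GeometryError(
            f"masks do not share a grid: {gt.shape}/{gt.spacing} vs "
            f"{test.shape}/{test.spacing}"
        )


def bounding_box_union(gt: BinaryMask, test: BinaryMask) -> BoxRegion:
    """Smallest axis-aligned box enclosing every positive voxel of either mask.

    Raises :class:`DegenerateInputError` if both masks are empty — there is
    no region to evaluate and no clinically meaningful score.
    """
    _check_same_grid(gt, test)
    union = gt.voxels | test.voxels
    if not union.any():
        raise DegenerateInputError("both masks are empty; no bounding box exists")
    lo, hi = [], []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        hit = np.where(union.any(axis=other))[0]
        lo.append(int(hit[0]))
        hi.append(int(hit[-1]))
    return BoxRegion(tuple(lo), tuple(hi))


def confusion_counts(
    gt: BinaryMask, test: BinaryMask, region: BoxRegion | None = None
) -> ConfusionCounts:
    """TP/FP/FN/TN counted over voxels inside *region* only.

    *region* defaults to :func:`bounding_box_union`.  A region that excludes
    a positive voxel of either mask violates the contract (the box correction
    must not change TP, FP or FN) and raises ``ValueError``.
    """
    _check_same_grid(gt, test)
    if region is None:
        region = bounding_box_union(gt, test)
    if not region.contains_grid(gt.shape):
        raise ValueError(f"region {region} exceeds grid {gt.shape}")
    sl = region.slices
    g = gt.voxels[sl]
    t = test.voxels[sl]
    tp = int(np.count_nonzero(g & t))
    fp = int(np.count_nonzero(~g & t))
    fn = int(np.count_nonzero(g & ~t))
    tn = int(np.count_nonzero(~g & ~t))
    if tp + fn != gt.n_positive or tp + fp != test.n_positive:
        raise ValueError(
            "region excludes positive voxels; the bounding box must enclose "
            "all positives of both masks"
        )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, region=region)


def _ratio(num: float, den: float) -> float:
    return np.nan if den == 0 else num / den


def overlap_metrics(c: ConfusionCounts) -> OverlapMetrics:
    """The six overlap scores from confusion cardinalities; 0/0 -> NaN."""
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    return OverlapMetrics(
        dsc=_ratio(2 * tp, 2 * tp + fp + fn),
        jac=_ratio(tp, tp + fp + fn),
        tpr=_ratio(tp, tp + fn),
        tnr=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        ri=_ratio(tp + tn, tp + tn + fp + fn),
    )


def compare_overlap(gt: BinaryMask, test: BinaryMask) -> OverlapMetrics:
    """Bounding box, counts and metrics in one call."""
    return overlap_metrics(confusion_counts(gt, test))
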