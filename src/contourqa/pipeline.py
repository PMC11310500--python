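"""Directory-level drivers tying I/O, metrics and QA together.

On-disk cohort layout (flat or one subdirectory per patient):

    <patient>_ct.nii.gz                      CT image
    <patient>_<organ>_ground_truth.nii.gz    approved contour
    <patient>_<organ>_<method>.nii.gz        auto-segmented contour

Organ labels are matched against the closed 16-organ vocabulary (labels
may themselves contain underscores, e.g. ``cochlea_L``); everything after
the organ is the role/method token.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import distance, kde_qa, overlap
from .overlap import DegenerateInputError
from .tables import CohortMetricTable
from .volumes import ORGANS, BinaryMask, ImageVolume, read_mask, read_volume

__all__ = [
    "parse_mask_filename",
    "scan_masks",
    "contour_metrics",
    "compare_directories",
    "build_baselines_from_cohort",
    "qa_patient",
]

log = logging.getLogger("contourqa")


def parse_mask_filename(path: str | Path) -> tuple[str, str, str] | None:
    """``<patient>_<organ>_<role>.nii(.gz)`` -> (patient, organ, role).

    Returns None for files that do not follow the convention (e.g. the
    ``_ct`` image) or whose organ token is outside the vocabulary.
    """
    name = Path(path).name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    else:
        return None
    if "_" not in name:
        return None
    pid, rest = name.split("_", 1)
    for organ in sorted(ORGANS, key=len, reverse=True):
        if rest == organ:  # a mask with no role token: treat as ground truth
            return pid, organ, "ground_truth"
        if rest.startswith(organ + "_"):
            return pid, organ, rest[len(organ) + 1 :]
    return None


def scan_masks(directory: str | Path) -> pd.DataFrame:
    """Recursively index mask files by (patient, organ, role)."""
    rows = []
    for path in sorted(Path(directory).rglob("*.nii*")):
        parsed = parse_mask_filename(path)
        if parsed is not None:
            rows.append([*parsed, path])
    return pd.DataFrame(rows, columns=["patient_id", "organ", "role", "path"])


def find_image(directory: str | Path, patient_id: str) -> Path | None:
    hits = sorted(Path(directory).rglob(f"{patient_id}_ct.nii*"))
    return hits[0] if hits else None


def contour_metrics(gt: BinaryMask, test: BinaryMask) -> dict[str, float]:
    """All 13 metrics for one contour pair; NaN where undefined.

    Overlap metrics need at least one non-empty mask; the distance family
    needs both surfaces to exist.
    """
    out: dict[str, float] = {}
    try:
        out.update(overlap.compare_overlap(gt, test).as_dict())
    except DegenerateInputError:
        out.update({m: np.nan for m in ("DSC", "JAC", "TPR", "TNR", "RI", "PPV")})
    if gt.is_empty or test.is_empty:
        out.update({m: np.nan for m in ("HD_std", "HD_min", "HD_median", "HD_mean", "MDA", "HD_95", "HD_max")})
    else:
        out.update(distance.compare_distance(gt, test).as_dict())
    return out


def compare_directories(
    gt_dir: str | Path,
    test_dir: str | Path,
    method: str | None = None,
) -> CohortMetricTable:
    """Score every test contour in *test_dir* against its ground truth.

    With *method* only that role is scored; otherwise every non-ground-truth
    role found.  Pairs whose ground truth is missing are skipped with a log
    message.
    """
    gt_index = scan_masks(gt_dir)
    gt_index = gt_index[gt_index["role"] == "ground_truth"]
    test_index = scan_masks(test_dir)
    test_index = test_index[test_index["role"] != "ground_truth"]
    if method is not None:
        test_index = test_index[test_index["role"] == method]
    table = CohortMetricTable()
    gt_lookup = {(r.patient_id, r.organ): r.path for r in gt_index.itertuples()}
    for rec in test_index.itertuples():
        gt_path = gt_lookup.get((rec.patient_id, rec.organ))
        if gt_path is None:
            log.warning("no ground truth for %s/%s; skipping", rec.patient_id, rec.organ)
            continue
        gt = read_mask(gt_path, organ=rec.organ, role="ground_truth")
        test = read_mask(rec.path, geometry=gt, organ=rec.organ, role=rec.role)
        for metric, value in contour_metrics(gt, test).items():
            table.add(rec.patient_id, rec.organ, rec.role, metric, value)
    return table


def build_baselines_from_cohort(
    cohort_dir: str | Path,
    grid: kde_qa.KDEGrid | None = None,
    bandwidth: float | str = "auto",
) -> dict[str, kde_qa.BaselineKDE]:
    """Per-organ mean-KDE baselines from every ground-truth contour found.

    Each patient contributes one KDE per organ, fitted from the HU values
    inside the approved contour on that patient's CT.
    """
    if grid is None:
        grid = kde_qa.KDEGrid.from_range(*kde_qa.DEFAULT_GRID)
    index = scan_masks(cohort_dir)
    index = index[index["role"] == "ground_truth"]
    curves: dict[str, list[kde_qa.KDECurve]] = {}
    images: dict[str, ImageVolume] = {}
    for rec in index.itertuples():
        if rec.patient_id not in images:
            img_path = find_image(cohort_dir, rec.patient_id)
            if img_path is None:
                log.warning("no CT for %s; skipping its contours", rec.patient_id)
                images[rec.patient_id] = None  # type: ignore[assignment]
                continue
            images[rec.patient_id] = read_volume(img_path)
        image = images[rec.patient_id]
        if image is None:
            continue
        mask = read_mask(rec.path, geometry=image, organ=rec.organ)
        if mask.is_empty:
            log.warning("empty ground truth %s/%s; skipping", rec.patient_id, rec.organ)
            continue
        sample = kde_qa.extract_hu(image, mask)
        curves.setdefault(rec.organ, []).append(
            kde_qa.fit_kde(sample, grid, bandwidth=bandwidth)
        )
    baselines = {}
    for organ, cs in curves.items():
        if len(cs) < 2:
            log.warning("organ %s has %d reference curve(s); skipped", organ, len(cs))
            continue
        baselines[organ] = kde_qa.build_baseline(cs, organ=organ)
    return baselines


def qa_patient(
    image_path: str | Path,
    masks_dir: str | Path,
    baselines: dict[str, kde_qa.BaselineKDE],
    threshold: float = 1.0,
    support_only: bool = False,
) -> kde_qa.AgreementReport:
    """QA every (non-ground-truth) contour found for one patient's CT."""
    image = read_volume(image_path)
    index = scan_masks(masks_dir)
    index = index[index["role"] != "ground_truth"]
    frames = []
    for role, group in index.groupby("role"):
        masks = [
            read_mask(r.path, geometry=image, organ=r.organ, role=role)
            for r in group.itertuples()
        ]
        pid = group["patient_id"].iloc[0]
        rep = kde_qa.qa_contour_set(
            image,
            masks,
            baselines,
            threshold=threshold,
            patient_id=pid,
            method=str(role),
            support_only=support_only,
        )
        frames.append(rep.rows)
    rows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=kde_qa.AgreementReport.COLUMNS)
    )
    return kde_qa.AgreementReport(rows=rows)
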