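"""Nuclear segmentation, leakage scoring, per-cell QC, detection assignment.

Masks are 2-D integer-labeled images (0 = background, labels consecutive from
1).  The leakage score of a nucleus is the mean far-red (642 nm) intensity in
a ring of configurable width around the nuclear mask divided by the nuclear
mean intensity; cytoplasmic receiver signal inflates it, and nuclei scoring
above a threshold (default 0.7) are rejected.  Coordinates are row-major
(y, x), 0-based, with pixel centers at integer positions; a detection belongs
to the mask pixel at (floor(y), floor(x)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from ._validation import ValidationError, check_int_min, check_nonneg

logger = logging.getLogger(__name__)

#: sentinel leakage score for undefined ratios (empty ring / zero nuclear
#: mean); infinite, so it fails any finite leakage threshold
LEAKAGE_UNDEFINED = float("inf")

EDGES = ("top", "bottom", "left", "right")


@dataclass
class NucleusRecord:
    """One segmented nucleus with its QC-relevant statistics."""

    label: int
    mask: np.ndarray  # boolean, full image shape
    area: int
    leakage_score: float = float("nan")
    detection_count: int = 0
    touches_edges: tuple[str, ...] = ()
    qc_pass: bool = True
    failure_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError(f"nucleus {self.label}: area must be positive")


@dataclass(frozen=True)
class QCParams:
    """Cell-level filters.  ``None`` disables a filter.

    ``count_bounds`` may be an explicit (low, high) pair or ``"auto"`` for the
    Tukey fence [Q1 - 1.5 IQR, Q3 + 1.5 IQR] computed over the nuclei being
    filtered.
    """

    min_area: float | None = 5000.0
    max_leakage: float | None = 0.7
    count_bounds: tuple[float, float] | str | None = "auto"
    exclude_edges: tuple[str, ...] | None = ("top", "bottom")

    def __post_init__(self) -> None:
        if self.exclude_edges is not None:
            bad = set(self.exclude_edges) - set(EDGES)
            if bad:
                raise ValidationError(f"unknown edges in exclude_edges: {sorted(bad)}")


def segment_nuclei_threshold(
    image: np.ndarray, smoothing_sigma: float = 10.0, min_area: int = 5000
) -> np.ndarray:
    """Threshold-based nuclear segmentation.

    Gaussian smoothing, Otsu global threshold, 8-connected component
    labeling, removal of components smaller than ``min_area`` pixels;
    surviving labels are renumbered consecutively from 1.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    check_nonneg("smoothing_sigma", smoothing_sigma)
    check_int_min("min_area", min_area, 0)

    smoothed = filters.gaussian(image, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        logger.warning("flat image: no nuclei segmented")
        return np.zeros(image.shape, dtype=np.uint16)
    thresh = filters.threshold_otsu(smoothed)
    labels = measure.label(smoothed > thresh, connectivity=2)
    if min_area > 0 and labels.max() > 0:
        # drop components strictly smaller than min_area
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_area)
        labels[np.isin(labels, small)] = 0
    relabeled = measure.label(labels > 0, connectivity=2)
    return relabeled.astype(np.uint16)


def leakage_score(
    intensity_642: np.ndarray,
    nucleus: NucleusRecord,
    all_nuclei_mask: np.ndarray | None = None,
    ring_width: int = 4,
) -> float:
    """Mean far-red intensity in a ring around the nucleus over nuclear mean.

    The ring is the morphological dilation of the mask by ``ring_width``
    (disk-shaped footprint) minus the mask, clipped to the image and with
    pixels belonging to any other nucleus excluded.  Undefined ratios (empty
    ring, zero nuclear mean) return :data:`LEAKAGE_UNDEFINED`.
    """
    check_int_min("ring_width", ring_width, 1)
    img = np.asarray(intensity_642, dtype=float)
    mask = nucleus.mask.astype(bool)
    if not mask.any():
        raise ValidationError(f"nucleus {nucleus.label}: empty mask")
    ring = ndimage.binary_dilation(mask, structure=morphology.disk(ring_width)) & ~mask
    if all_nuclei_mask is not None:
        ring &= ~(np.asarray(all_nuclei_mask) > 0)
    if not ring.any():
        return LEAKAGE_UNDEFINED
    nuclear_mean = img[mask].mean()
    if nuclear_mean == 0:
        return LEAKAGE_UNDEFINED
    return float(img[ring].mean() / nuclear_mean)


def records_from_mask(
    labeled_mask: np.ndarray,
    intensity_642: np.ndarray | None = None,
    ring_width: int = 4,
) -> list[NucleusRecord]:
    """Build :class:`NucleusRecord` objects (area, edges, leakage) from a mask."""
    labeled_mask = np.asarray(labeled_mask)
    nrows, ncols = labeled_mask.shape
    records = []
    for label in np.unique(labeled_mask):
        if label == 0:
            continue
        mask = labeled_mask == label
        edges = []
        if mask[0, :].any():
            edges.append("top")
        if mask[-1, :].any():
            edges.append("bottom")
        if mask[:, 0].any():
            edges.append("left")
        if mask[:, -1].any():
            edges.append("right")
        rec = NucleusRecord(
            label=int(label),
            mask=mask,
            area=int(mask.sum()),
            touches_edges=tuple(edges),
        )
        if intensity_642 is not None:
            rec.leakage_score = leakage_score(
                intensity_642, rec, all_nuclei_mask=labeled_mask, ring_width=ring_width
            )
        records.append(rec)
    return records


def _auto_count_bounds(counts: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(counts, [25, 75])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def apply_qc(
    nuclei: list[NucleusRecord], params: QCParams = QCParams()
) -> tuple[list[NucleusRecord], dict]:
    """Apply the cell-level filters; return retained nuclei and a QC report.

    Filters (each optional): area strictly below ``min_area`` excluded;
    leakage strictly above ``max_leakage`` excluded; detection count outside
    ``count_bounds`` excluded; nuclei touching any edge in ``exclude_edges``
    excluded.  Every record's ``qc_pass``/``failure_reasons`` fields are
    updated in place and the report lists each exclusion with its reasons.
    """
    bounds = params.count_bounds
    if bounds == "auto":
        if len(nuclei) == 0:
            bounds = None
        else:
            bounds = _auto_count_bounds(
                np.array([n.detection_count for n in nuclei], dtype=float)
            )

    retained = []
    report: dict = {"params": {
        "min_area": params.min_area,
        "max_leakage": params.max_leakage,
        "count_bounds": list(bounds) if bounds is not None else None,
        "exclude_edges": list(params.exclude_edges or ()),
    }, "nuclei": {}}
    for rec in nuclei:
        reasons = []
        if params.min_area is not None and rec.area < params.min_area:
            reasons.append(f"area {rec.area} < {params.min_area}")
        if params.max_leakage is not None and not (
            rec.leakage_score <= params.max_leakage
        ):
            reasons.append(f"leakage {rec.leakage_score} > {params.max_leakage}")
        if bounds is not None and not (
            bounds[0] <= rec.detection_count <= bounds[1]
        ):
            reasons.append(
                f"detection count {rec.detection_count} outside "
                f"[{bounds[0]:g}, {bounds[1]:g}]"
            )
        if params.exclude_edges:
            hit = sorted(set(rec.touches_edges) & set(params.exclude_edges))
            if hit:
                reasons.append(f"touches excluded edge(s): {', '.join(hit)}")
        rec.qc_pass = not reasons
        rec.failure_reasons = reasons
        report["nuclei"][rec.label] = {
            "area": rec.area,
            "leakage": rec.leakage_score,
            "count": rec.detection_count,
            "reasons": reasons,
        }
        if rec.qc_pass:
            retained.append(rec)
    return retained, report


def assign_detections(
    detections: pd.DataFrame, labeled_mask: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Assign each detection (and its trajectory) to a nucleus label.

    A detection gets the label of the mask pixel at (floor(y), floor(x));
    out-of-bounds detections get label 0 and are counted in the report.  A
    trajectory inherits the label of its first (earliest-frame) detection via
    the ``traj_nucleus`` column.
    """
    labeled_mask = np.asarray(labeled_mask)
    nrows, ncols = labeled_mask.shape
    out = detections.copy()
    if len(out) == 0:
        out["nucleus"] = np.array([], dtype=np.int64)
        out["traj_nucleus"] = np.array([], dtype=np.int64)
        return out, {"n_out_of_bounds": 0, "n_unassigned": 0}

    iy = np.floor(out["y"].to_numpy(dtype=float)).astype(np.int64)
    ix = np.floor(out["x"].to_numpy(dtype=float)).astype(np.int64)
    in_bounds = (iy >= 0) & (iy < nrows) & (ix >= 0) & (ix < ncols)
    labels = np.zeros(len(out), dtype=np.int64)
    labels[in_bounds] = labeled_mask[iy[in_bounds], ix[in_bounds]]
    out["nucleus"] = labels

    first = (
        out.sort_values(["trajectory", "frame"], kind="stable")
        .groupby("trajectory", sort=False)["nucleus"]
        .first()
    )
    out["traj_nucleus"] = out["trajectory"].map(first).astype(np.int64)
    report = {
        "n_out_of_bounds": int((~in_bounds).sum()),
        "n_unassigned": int((labels == 0).sum()),
    }
    return out, report


def count_detections_per_nucleus(
    assigned: pd.DataFrame, records: list[NucleusRecord]
) -> None:
    """Populate ``detection_count`` on each record from an assigned table."""
    counts = assigned["nucleus"].value_counts()
    for rec in records:
        rec.detection_count = int(counts.get(rec.label, 0))
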