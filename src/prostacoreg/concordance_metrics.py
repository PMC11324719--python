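"""Concordance statistics between imaging ROIs and ground-truth lesions.

Pixel-level metrics (overlap, false positive, dice, per-slide sensitivity)
are computed on binary masks sharing one rasterization grid; detection is
scored at the patient level (index lesion) and the cross-section level, with
a completely-false flag for ROIs touching no clinically significant lesion
cross-section. Only grade group >= 2 lesions count as significant.
Aggregation reports per-group mean ± standard error alongside pooled
fractions. Specificity is deliberately not reported; the false-positive
percentage is its surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SIGNIFICANT_GRADE_GROUP = 2  # grade group >= 2 is clinically significant


@dataclass
class LesionCrossSection:
    """One lesion's 2D footprint on a WM slide, as a binary mask on the shared grid."""

    slide_id: str
    lesion_id: str
    mask: np.ndarray
    pixel_area_mm2: float
    grade_group: int
    is_index: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 1 <= self.grade_group <= 5:
            raise ValueError("grade_group must be in 1..5")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum() * self.pixel_area_mm2)

    @property
    def significant(self) -> bool:
        return self.grade_group >= SIGNIFICANT_GRADE_GROUP


def _as_mask(m) -> np.ndarray:
    return np.asarray(getattr(m, "mask", m), dtype=bool)


def overlap_percent(lesion, roi) -> float:
    """Percentage of the lesion covered by the ROI: 100 * |lesion ∩ roi| / |lesion|."""
    les, r = _as_mask(lesion), _as_mask(roi)
    n_lesion = les.sum()
    if n_lesion == 0:
        raise ValueError("empty lesion mask")
    return 100.0 * np.logical_and(les, r).sum() / n_lesion


def false_positive_percent(lesion, roi) -> float:
    """Percentage of the ROI not covering lesion: 100 * (1 - |lesion ∩ roi| / |roi|)."""
    les, r = _as_mask(lesion), _as_mask(roi)
    n_roi = r.sum()
    if n_roi == 0:
        raise ValueError("empty ROI mask")
    return 100.0 * (1.0 - np.logical_and(les, r).sum() / n_roi)


def dice_percent(lesion, roi) -> float:
    """Dice similarity on the percent scale: 100 * 2|∩| / (|lesion| + |roi|)."""
    les, r = _as_mask(lesion), _as_mask(roi)
    denom = les.sum() + r.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return 100.0 * 2.0 * np.logical_and(les, r).sum() / denom


def slide_sensitivity(lesion_masks: list, roi_masks: list) -> float:
    """Per-slide sensitivity: lesion foci on a slide are unioned before scoring."""
    if not lesion_masks:
        raise ValueError("no lesions on slide: sensitivity not applicable")
    les = np.logical_or.reduce([_as_mask(m) for m in lesion_masks])
    if les.sum() == 0:
        raise ValueError("lesion union is empty")
    if roi_masks:
        roi = np.logical_or.reduce([_as_mask(m) for m in roi_masks])
    else:
        roi = np.zeros_like(les)
    return 100.0 * np.logical_and(les, roi).sum() / les.sum()


# ---------------------------------------------------------------------------
# detection


@dataclass
class DetectionRecord:
    subject_id: str
    reviewer_id: str
    modality: str
    level: str  # patient | cross_section | pixel
    hits: int
    opportunities: int
    completely_false_rois: int = 0
    total_rois: int = 0
    item_values: list = field(default_factory=list)  # per-item metric values (pixel level)

    def __post_init__(self) -> None:
        if self.hits < 0 or self.opportunities < 0 or self.hits > self.opportunities:
            raise ValueError("need 0 <= hits <= opportunities")

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.hits / self.opportunities if self.opportunities else 0.0


def _intersects(a, b) -> bool:
    return bool(np.logical_and(_as_mask(a), _as_mask(b)).any())


def detect_hits(
    lesions: list[LesionCrossSection],
    rois: list,
    level: str,
    subject_id: str = "",
    reviewer_id: str = "",
    modality: str = "microUS",
) -> DetectionRecord:
    """Score detections: any ROI/lesion mask intersection counts as a hit.

    Patient level: the index lesion is hit iff any ROI on any slide touches
    any of its cross-sections. Cross-section level: each significant
    cross-section is hit iff an ROI on its slide touches it. In both cases an
    ROI touching no significant cross-section on its slide is flagged
    completely false. Lesions below grade group 2 are filtered out first.
    """
    if level not in ("patient", "cross_section"):
        raise ValueError("level must be 'patient' or 'cross_section'")
    significant = [l for l in lesions if l.significant]

    def rois_on(slide_id):
        return [r for r in rois if r.slide_id == slide_id]

    completely_false = sum(
        1
        for r in rois
        if not any(
            _intersects(l, r) for l in significant if l.slide_id == r.slide_id
        )
    )

    if level == "patient":
        index_sections = [l for l in significant if l.is_index]
        if not index_sections:
            raise ValueError("no index lesion cross-sections present")
        hit = any(
            _intersects(l, r)
            for l in index_sections
            for r in rois_on(l.slide_id)
        )
        return DetectionRecord(
            subject_id, reviewer_id, modality, "patient",
            hits=int(hit), opportunities=1,
            completely_false_rois=completely_false, total_rois=len(rois),
        )

    hits = sum(
        1
        for l in significant
        if any(_intersects(l, r) for r in rois_on(l.slide_id))
    )
    return DetectionRecord(
        subject_id, reviewer_id, modality, "cross_section",
        hits=hits, opportunities=len(significant),
        completely_false_rois=completely_false, total_rois=len(rois),
    )


# ---------------------------------------------------------------------------
# aggregation


def mean_se(values) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(n), sample sd); SE is 0 for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty group")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def pooled_fraction_percent(hits: int, opportunities: int) -> float:
    if opportunities <= 0:
        raise ValueError("opportunities must be positive")
    if not 0 <= hits <= opportunities:
        raise ValueError("need 0 <= hits <= opportunities")
    return 100.0 * hits / opportunities


@dataclass
class MetricsReport:
    groups: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config, "groups": self.groups}


def aggregate(
    records: list[DetectionRecord],
    by: str = "modality",
    area_bins: list[float] | None = None,
    areas_mm2: dict | None = None,
    excluded_reviewers: tuple[str, ...] = (),
) -> MetricsReport:
    """Group detection records and report mean ± SE plus pooled fractions.

    ``by`` is "modality" or "reviewer". Reviewer exclusions are a declared
    configuration choice and are echoed into the report. When area
    stratification is requested the per-record item values are binned by
    their cross-sectional areas before averaging.
    """
    if not records:
        raise ValueError("no records to aggregate")
    if by not in ("modality", "reviewer"):
        raise ValueError("by must be 'modality' or 'reviewer'")
    records = [r for r in records if r.reviewer_id not in excluded_reviewers]
    if not records:
        raise ValueError("all records excluded")

    keyfn = (lambda r: r.modality) if by == "modality" else (lambda r: r.reviewer_id)
    report = MetricsReport(
        config={
            "group_by": by,
            "excluded_reviewers": list(excluded_reviewers),
            "area_bins_mm2": area_bins,
        }
    )
    for key in sorted({keyfn(r) for r in records}):
        group = [r for r in records if keyfn(r) == key]
        rates = [r.rate_percent for r in group if r.opportunities]
        mean, se = mean_se(rates)
        hits = sum(r.hits for r in group)
        opps = sum(r.opportunities for r in group)
        cf = sum(r.completely_false_rois for r in group)
        n_rois = sum(r.total_rois for r in group)
        entry = {
            "n_records": len(group),
            "mean_percent": mean,
            "se_percent": se,
            "se_flag_single": len(rates) == 1,
            "pooled_hits": hits,
            "pooled_opportunities": opps,
            "pooled_percent": pooled_fraction_percent(hits, opps) if opps else None,
            "completely_false_rois": cf,
            "total_rois": n_rois,
            "completely_false_percent": (
                pooled_fraction_percent(cf, n_rois) if n_rois else None
            ),
        }
        item_values = [v for r in group for v in r.item_values]
        if item_values:
            vm, vs = mean_se(item_values)
            entry["item_mean_percent"] = vm
            entry["item_se_percent"] = vs
        report.groups[key] = entry
    return report


def stratify_by_area(
    values: list[float],
    areas_mm2: list[float],
    bin_edges_mm2: list[float] | None = None,
) -> dict:
    """Bin per-cross-section metric values by cross-sectional area.

    Default bins are the quartiles of the observed areas; edges are echoed in
    the output so the stratification is always declared.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(areas_mm2, dtype=float)
    if v.shape != a.shape or v.size == 0:
        raise ValueError("values and areas must be nonempty and aligned")
    if bin_edges_mm2 is None:
        bin_edges_mm2 = list(np.quantile(a, [0.25, 0.5, 0.75]))
    edges = [-np.inf, *bin_edges_mm2, np.inf]
    out = {"bin_edges_mm2": list(bin_edges_mm2), "bins": []}
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (a > lo) & (a <= hi)
        entry = {"lo_mm2": lo, "hi_mm2": hi, "n": int(sel.sum())}
        if sel.any():
            m, s = mean_se(v[sel])
            entry.update(mean_percent=m, se_percent=s)
        out["bins"].append(entry)
    return out


def round_display(value: float, kind: str = "percent") -> float:
    """Display rounding: one decimal for percentages, two for mm."""
    return round(value, 1 if kind == "percent" else 2)
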