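"""Detector evaluation against human annotations with temporal-overlap criteria.

Precision and recall are defined by fractional temporal overlap rather
than exact interval matches:

* a reported detection is a **true positive** if it overlaps at least
  60% of the duration of some annotation of the same species in the same
  recording (evaluated per annotation — a detection straddling several
  annotations must reach 60% of at least one);
* an annotation is **recalled** if the union of its intersections with
  all reported detections covers at least 50% of its duration.

Both thresholds are inclusive ("at least").  Matching is class-aware: a
species-label mismatch never matches.  Many-to-one matching is allowed
(several detections may be true positives against one annotation).

Because a recognizer can find real calls the human annotators missed,
the reference set is tiered: the *base* tier is human annotations only;
*base + confirmed* adds model detections a reviewer confirmed as real;
*base + unable-to-reject* further adds detections a reviewer could
neither confirm nor reject.  True performance is bracketed by the last
two tiers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .segdetect import DetectionEvent

__all__ = [
    "Annotation",
    "EvalReport",
    "TIERS",
    "label_detections_for_precision",
    "label_annotations_for_recall",
    "build_tiers",
    "evaluate_tier",
    "evaluate_all_tiers",
    "select_focal_species",
]

logger = logging.getLogger(__name__)

TIERS = ("base", "base_confirmed", "base_unable_to_reject")

ANNOTATION_ORIGINS = ("human", "confirmed_detection", "unable_to_reject_detection")

#: inclusive overlap fractions for the two matching criteria
PRECISION_OVERLAP_FRACTION = 0.60
RECALL_COVERAGE_FRACTION = 0.50

#: focal-species inclusion thresholds, applied to the base+confirmed tier
FOCAL_MIN_PRECISION = 0.84
FOCAL_MIN_ANNOTATIONS = 20
FOCAL_MIN_RECALL = 0.30


@dataclass(frozen=True)
class Annotation:
    """A labelled call interval: human-made or a vetted model detection."""

    recording_id: str
    start: float
    end: float
    species: str
    origin: str = "human"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"annotation end ({self.end}) must exceed start ({self.start})"
            )
        if self.origin not in ANNOTATION_ORIGINS:
            raise ValueError(f"unknown annotation origin {self.origin!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class EvalReport:
    """Per-species precision/recall for one evaluation tier.

    ``precision`` is None when there are no detections and ``recall`` is
    None when there are no annotations (undefined, not zero).
    """

    tier: str
    species: str
    n_detections: int
    n_annotations: int
    true_positives: int
    recalled: int
    precision: float | None
    recall: float | None


def _overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def _same_stream(det: DetectionEvent, ann: Annotation) -> bool:
    return det.recording_id == ann.recording_id and det.species == ann.species


def label_detections_for_precision(
    detections: Sequence[DetectionEvent],
    annotations: Sequence[Annotation],
    min_fraction: float = PRECISION_OVERLAP_FRACTION,
) -> list[bool]:
    """True-positive flag per detection under the 60%-of-annotation rule."""
    labels = []
    for det in detections:
        tp = any(
            _same_stream(det, ann)
            and _overlap(det.start, det.end, ann.start, ann.end)
            >= min_fraction * ann.duration
            for ann in annotations
        )
        labels.append(tp)
    return labels


def label_annotations_for_recall(
    annotations: Sequence[Annotation],
    detections: Sequence[DetectionEvent],
    min_coverage: float = RECALL_COVERAGE_FRACTION,
) -> list[bool]:
    """Recalled flag per annotation under the 50%-union-coverage rule."""
    labels = []
    for ann in annotations:
        pieces = sorted(
            (max(det.start, ann.start), min(det.end, ann.end))
            for det in detections
            if _same_stream(det, ann) and det.start < ann.end and det.end > ann.start
        )
        covered = 0.0
        cursor = -math.inf
        for lo, hi in pieces:
            lo = max(lo, cursor)
            if hi > lo:
                covered += hi - lo
                cursor = hi
        labels.append(covered >= min_coverage * ann.duration - 1e-12)
    return labels


def _as_annotation(det: DetectionEvent, origin: str) -> Annotation:
    # a reviewer may redraw the true call's bounds while confirming, via
    # metadata; the annotation then need not coincide with the detection,
    # which is how recall can drop when the reference set is augmented
    return Annotation(
        recording_id=det.recording_id,
        start=det.metadata.get("annotated_start", det.start),
        end=det.metadata.get("annotated_end", det.end),
        species=det.species,
        origin=origin,
    )


def build_tiers(
    base_annotations: Sequence[Annotation],
    detections: Sequence[DetectionEvent],
) -> dict[str, list[Annotation]]:
    """Construct the three nested reference tiers.

    ``base`` is the human annotation set; ``base_confirmed`` adds
    reviewer-confirmed detections as annotations; ``base_unable_to_reject``
    further adds detections the reviewer could not reject.  Rejected
    detections never enter a tier; unreviewed detections trigger a
    warning and are treated as rejected for tier construction.
    """
    n_unreviewed = sum(1 for d in detections if d.review_status == "unreviewed")
    if n_unreviewed:
        logger.warning(
            "%d unreviewed detections treated as rejected for tier construction",
            n_unreviewed,
        )
    base = list(base_annotations)
    confirmed = [
        _as_annotation(d, "confirmed_detection")
        for d in detections
        if d.review_status == "confirmed"
    ]
    unable = [
        _as_annotation(d, "unable_to_reject_detection")
        for d in detections
        if d.review_status == "unable_to_reject"
    ]
    return {
        "base": base,
        "base_confirmed": base + confirmed,
        "base_unable_to_reject": base + confirmed + unable,
    }


def evaluate_tier(
    annotations: Sequence[Annotation],
    detections: Sequence[DetectionEvent],
    tier: str = "base",
    species: str | None = None,
) -> EvalReport:
    """Precision and recall of ``detections`` against one reference tier.

    With ``species=None`` all events are pooled; otherwise both sets are
    restricted to that species first.
    """
    if species is not None:
        annotations = [a for a in annotations if a.species == species]
        detections = [d for d in detections if d.species == species]
    tp_flags = label_detections_for_precision(detections, annotations)
    rec_flags = label_annotations_for_recall(annotations, detections)
    n_det, n_ann = len(detections), len(annotations)
    tp, rec = sum(tp_flags), sum(rec_flags)
    return EvalReport(
        tier=tier,
        species=species if species is not None else "(all)",
        n_detections=n_det,
        n_annotations=n_ann,
        true_positives=tp,
        recalled=rec,
        precision=tp / n_det if n_det else None,
        recall=rec / n_ann if n_ann else None,
    )


def evaluate_all_tiers(
    base_annotations: Sequence[Annotation],
    detections: Sequence[DetectionEvent],
    species: Iterable[str] | None = None,
) -> list[EvalReport]:
    """Per-species reports for every tier (the evaluation-grid shape)."""
    tiers = build_tiers(base_annotations, detections)
    if species is None:
        species = sorted(
            {a.species for a in base_annotations} | {d.species for d in detections}
        )
    return [
        evaluate_tier(tiers[tier], detections, tier=tier, species=sp)
        for sp in species
        for tier in TIERS
    ]


def select_focal_species(
    reports: Iterable[EvalReport],
    min_precision: float = FOCAL_MIN_PRECISION,
    min_annotations: int = FOCAL_MIN_ANNOTATIONS,
    min_recall: float = FOCAL_MIN_RECALL,
) -> list[str]:
    """Species meeting the inclusion criteria on the base+confirmed tier.

    A species qualifies when its base+confirmed precision, reference-set
    size and recall all meet the (inclusive) thresholds.  Reports from
    other tiers are ignored.
    """
    focal = []
    for r in reports:
        if r.tier != "base_confirmed":
            continue
        if (
            r.precision is not None
            and r.recall is not None
            and r.precision >= min_precision
            and r.n_annotations >= min_annotations
            and r.recall >= min_recall
        ):
            focal.append(r.species)
    return sorted(set(focal))
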