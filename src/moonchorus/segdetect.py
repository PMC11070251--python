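"""Detector segment-score post-processing.

A recognizer scores short, overlapped audio segments with a per-species
confidence in [0, 1].  Two downstream conventions are supported:

* **test mode** — segments of 0.8 s advanced by 0.2 s (0.6 s overlap);
  contiguous above-threshold segments are merged into single detection
  events so they can be compared against human annotations.
* **field mode** — segments advanced by 0.4 s; no merging, the response
  is simply the number of above-threshold segments per 10 min recording.

"Above threshold" is strict (``score > threshold``) by default; the
comparison is configurable because the convention is a genuine choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import ParameterError

__all__ = [
    "SegmentScore",
    "DetectionEvent",
    "ParameterError",
    "segment_grid",
    "merge_contiguous",
    "count_field_detections",
]

#: review states a human can assign to a reported detection
REVIEW_STATUSES = ("unreviewed", "confirmed", "unable_to_reject", "rejected")

#: default segment geometry (seconds)
DEFAULT_SEGMENT_LENGTH = 0.8
DEFAULT_TEST_ADVANCE = 0.2  # 0.6 s overlap between successive segments
DEFAULT_FIELD_ADVANCE = 0.4
DEFAULT_THRESHOLD = 0.95

_EPS = 1e-9


@dataclass(frozen=True)
class SegmentScore:
    """One recognizer output for a fixed-length window of one recording."""

    recording_id: str
    start: float
    end: float
    species: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ParameterError(f"score must be in [0, 1], got {self.score}")
        if self.end <= self.start:
            raise ParameterError("segment end must exceed start")


@dataclass(frozen=True)
class DetectionEvent:
    """A merged run of above-threshold segments reported as one call.

    ``review_status`` records the outcome of optional human vetting of
    the event; freshly merged events are ``unreviewed``.
    """

    recording_id: str
    start: float
    end: float
    species: str
    peak_score: float
    review_status: str = "unreviewed"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError("event end must exceed start")
        if self.review_status not in REVIEW_STATUSES:
            raise ParameterError(
                f"review_status must be one of {REVIEW_STATUSES}, "
                f"got {self.review_status!r}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


def segment_grid(
    recording_duration: float,
    segment_length: float = DEFAULT_SEGMENT_LENGTH,
    advance: float = DEFAULT_TEST_ADVANCE,
) -> list[tuple[float, float]]:
    """Tile a recording with fixed-length segments at a constant hop.

    Segments start at ``0, advance, 2*advance, ...``; the last segment
    must end within the recording.  ``advance == segment_length`` gives a
    non-overlapping tiling; smaller advances overlap.

    Returns a list of half-open ``(start, end)`` intervals in seconds.
    """
    if advance <= 0:
        raise ParameterError(f"advance must be positive, got {advance}")
    if segment_length < advance:
        raise ParameterError("segment_length must be >= advance")
    if segment_length > recording_duration + _EPS:
        raise ParameterError("segment_length exceeds recording duration")
    grid: list[tuple[float, float]] = []
    k = 0
    while k * advance + segment_length <= recording_duration + _EPS:
        start = k * advance
        grid.append((start, start + segment_length))
        k += 1
    return grid


def _passes(score: float, threshold: float, strict: bool) -> bool:
    return score > threshold if strict else score >= threshold


def merge_contiguous(
    scores: Iterable[SegmentScore],
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> list[DetectionEvent]:
    """Merge runs of contiguous above-threshold segments into events.

    Segments whose intervals overlap or share an endpoint are contiguous;
    a below-threshold segment between two runs breaks them apart.  Each
    maximal run becomes one :class:`DetectionEvent` spanning the union of
    its segments, summarized by the peak (maximum) score.

    Input order does not matter: segments are sorted internally (stable)
    and processed independently per ``(recording_id, species)`` stream,
    so overlapping detections of different species coexist.
    """
    surviving = [s for s in scores if _passes(s.score, threshold, strict)]
    surviving.sort(key=lambda s: (s.recording_id, s.species, s.start, s.end))

    events: list[DetectionEvent] = []
    run: list[SegmentScore] = []

    def _flush() -> None:
        if run:
            events.append(
                DetectionEvent(
                    recording_id=run[0].recording_id,
                    start=run[0].start,
                    end=max(s.end for s in run),
                    species=run[0].species,
                    peak_score=max(s.score for s in run),
                )
            )
            run.clear()

    for seg in surviving:
        if run and (
            seg.recording_id != run[0].recording_id
            or seg.species != run[0].species
            or seg.start > max(s.end for s in run) + _EPS
        ):
            _flush()
        run.append(seg)
    _flush()
    return events


def count_field_detections(
    scores: Iterable[SegmentScore],
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = True,
) -> dict[tuple[str, str], int]:
    """Count above-threshold segments per (recording, species), unmerged.

    This is the field-mode response variable: the number of segments with
    scores above the detection threshold within each recording window.
    No post-processing is applied, so a long call spanning several
    segments contributes several detections.
    """
    counts: dict[tuple[str, str], int] = {}
    for s in scores:
        key = (s.recording_id, s.species)
        counts.setdefault(key, 0)
        if _passes(s.score, threshold, strict):
            counts[key] += 1
    return counts
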