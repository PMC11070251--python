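"""File formats, recording schedules and pipeline configuration.

Annotation exchange uses Raven-style selection tables: tab-separated
text with a header, begin/end times in seconds from recording start and
a species/label column.  Column names are configurable with defaults
matching common Raven exports.  Count tables and segment scores travel
as plain CSV.  All readers and writers round-trip losslessly.

Time conventions: recording-window timestamps carry a fixed UTC offset
per site (schedule arithmetic happens in local civil time); intra-
recording intervals are half-open ``[start, end)`` seconds from the
window start.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import ConfigError, FormatError
from .evalmatch import Annotation
from .segdetect import DetectionEvent, SegmentScore
from .zicount import CountRecord

__all__ = [
    "RecordingWindow",
    "SiteConfig",
    "generate_schedule",
    "read_selection_table",
    "write_selection_table",
    "read_detection_table",
    "read_segment_scores",
    "write_segment_scores",
    "read_detection_counts",
    "write_detection_counts",
    "load_config",
    "configure_logging",
]

logger = logging.getLogger(__name__)

#: nightly duty cycle: a 10-min window at the top of each hour, 18:00-06:00
DEFAULT_NIGHT_START_HOUR = 18
DEFAULT_NIGHT_END_HOUR = 6
DEFAULT_WINDOW_DURATION = 600.0

#: default Raven selection-table column names
RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"
RAVEN_SPECIES = "Species"


def configure_logging(level: int = logging.INFO) -> None:
    """Basic stderr logging for CLI runs."""
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


@dataclass(frozen=True)
class SiteConfig:
    """A recording site: location, clock offset and operation periods."""

    site_id: str
    latitude: float
    longitude: float
    elevation: float = 0.0
    utc_offset: float = 0.0
    operation_intervals: tuple[tuple[date, date], ...] = ()

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ConfigError(f"latitude out of range: {self.latitude}")
        if abs(self.longitude) > 180:
            raise ConfigError(f"longitude out of range: {self.longitude}")
        for start, end in self.operation_intervals:
            if end < start:
                raise ConfigError(f"operation interval ends before it starts: "
                                  f"{start}..{end}")

    @property
    def tzinfo(self) -> timezone:
        return timezone(timedelta(hours=self.utc_offset))


@dataclass(frozen=True)
class RecordingWindow:
    """One scheduled recording: a site, a start instant and a duration."""

    site_id: str
    start: pd.Timestamp
    duration: float = DEFAULT_WINDOW_DURATION

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError(f"duration must be positive, got {self.duration}")

    @property
    def recording_id(self) -> str:
        return f"{self.site_id}_{pd.Timestamp(self.start).strftime('%Y%m%dT%H%M%S')}"


def _night_hours(night_start_hour: int, night_end_hour: int) -> list[int]:
    if not (0 <= night_start_hour <= 23 and 0 <= night_end_hour <= 23):
        raise ConfigError(
            f"hours must be in 0-23, got {night_start_hour}..{night_end_hour}"
        )
    if night_end_hour >= night_start_hour:
        return list(range(night_start_hour, night_end_hour + 1))
    return list(range(night_start_hour, 24)) + list(range(0, night_end_hour + 1))


def generate_schedule(
    site: SiteConfig,
    night_start_hour: int = DEFAULT_NIGHT_START_HOUR,
    night_end_hour: int = DEFAULT_NIGHT_END_HOUR,
    window_duration: float = DEFAULT_WINDOW_DURATION,
) -> list[RecordingWindow]:
    """Nightly top-of-hour recording windows for a site's operation periods.

    Each operational night (keyed by its evening date) gets one window at
    the top of every hour from ``night_start_hour`` through
    ``night_end_hour`` inclusive, wrapping past midnight when the end
    hour is smaller than the start hour.  The default 18:00-06:00 cycle
    yields 13 windows per night.  Times are local civil time at the
    site's fixed UTC offset.
    """
    if not site.operation_intervals:
        raise ConfigError(f"site {site.site_id!r} has no operation intervals")
    hours = _night_hours(night_start_hour, night_end_hour)
    windows = []
    for interval_start, interval_end in site.operation_intervals:
        night = interval_start
        while night <= interval_end:
            for h in hours:
                day = night if h >= night_start_hour else night + timedelta(days=1)
                start = pd.Timestamp(
                    datetime.combine(day, time(hour=h), tzinfo=site.tzinfo)
                )
                windows.append(
                    RecordingWindow(site.site_id, start, window_duration)
                )
            night += timedelta(days=1)
    return windows


# --------------------------------------------------------------------------
# Raven-style selection tables
# --------------------------------------------------------------------------

def read_selection_table(
    path,
    begin_col: str = RAVEN_BEGIN,
    end_col: str = RAVEN_END,
    species_col: str = RAVEN_SPECIES,
    recording_col: str = "Begin File",
    recording_id: str | None = None,
) -> list[Annotation]:
    """Read a tab-separated selection table into annotations.

    Required columns: begin time, end time and the species label; the
    recording is taken from ``recording_col`` when present, else from
    the ``recording_id`` argument.  Extra columns are preserved in each
    annotation's ``metadata``.  Rows with ``end <= begin`` are rejected.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in (begin_col, end_col, species_col):
            if col not in header:
                raise FormatError(f"selection table {path} missing column {col!r}")
        has_rec = recording_col in header
        annotations = []
        for i, row in enumerate(reader, start=2):
            try:
                begin, end = float(row[begin_col]), float(row[end_col])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path} line {i}: unparsable time") from exc
            if end <= begin:
                raise FormatError(
                    f"{path} line {i}: end time {end} <= begin time {begin}"
                )
            rec = row[recording_col] if has_rec else (recording_id or "")
            meta = {
                k: v
                for k, v in row.items()
                if k not in (begin_col, end_col, species_col, recording_col)
            }
            annotations.append(
                Annotation(
                    recording_id=rec,
                    start=begin,
                    end=end,
                    species=row[species_col],
                    metadata=meta,
                )
            )
    logger.info("read %d annotations from %s", len(annotations), path)
    return annotations


def write_selection_table(
    items: Sequence[Annotation] | Sequence[DetectionEvent],
    path,
    begin_col: str = RAVEN_BEGIN,
    end_col: str = RAVEN_END,
    species_col: str = RAVEN_SPECIES,
    recording_col: str = "Begin File",
) -> None:
    """Write annotations or detection events as a Raven-style table.

    Detection events additionally carry their peak score and review
    status so the table opens directly in annotation software.
    """
    path = Path(path)
    is_event = bool(items) and isinstance(items[0], DetectionEvent)
    extra = ["Score", "Review Status"] if is_event else []
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["Selection", recording_col, begin_col, end_col, species_col] + extra
        )
        for i, item in enumerate(items, start=1):
            row = [
                i,
                item.recording_id,
                repr(float(item.start)),
                repr(float(item.end)),
                item.species,
            ]
            if is_event:
                row += [repr(float(item.peak_score)), item.review_status]
            writer.writerow(row)
    logger.info("wrote %d rows to %s", len(items), path)


def read_detection_table(
    path,
    begin_col: str = RAVEN_BEGIN,
    end_col: str = RAVEN_END,
    species_col: str = RAVEN_SPECIES,
    recording_col: str = "Begin File",
) -> list[DetectionEvent]:
    """Read detection events from a selection table written by this package.

    Expects the ``Score`` column; ``Review Status`` defaults to
    ``unreviewed`` when absent so externally produced tables still load.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in (begin_col, end_col, species_col, "Score"):
            if col not in header:
                raise FormatError(f"detection table {path} missing column {col!r}")
        events = []
        for i, row in enumerate(reader, start=2):
            begin, end = float(row[begin_col]), float(row[end_col])
            if end <= begin:
                raise FormatError(f"{path} line {i}: end <= begin")
            events.append(
                DetectionEvent(
                    recording_id=row.get(recording_col, ""),
                    start=begin,
                    end=end,
                    species=row[species_col],
                    peak_score=float(row["Score"]),
                    review_status=row.get("Review Status", "unreviewed"),
                )
            )
    logger.info("read %d detection events from %s", len(events), path)
    return events


# --------------------------------------------------------------------------
# segment-score CSV
# --------------------------------------------------------------------------

_SCORE_COLUMNS = ["recording_id", "start", "end", "species", "score"]


def write_segment_scores(scores: Sequence[SegmentScore], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_SCORE_COLUMNS)
        for s in scores:
            writer.writerow(
                [s.recording_id, repr(float(s.start)), repr(float(s.end)),
                 s.species, repr(float(s.score))]
            )
    logger.info("wrote %d segment scores to %s", len(scores), path)


def read_segment_scores(path) -> list[SegmentScore]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in _SCORE_COLUMNS:
            if col not in (reader.fieldnames or []):
                raise FormatError(f"segment-score file {path} missing column {col!r}")
        scores = [
            SegmentScore(
                recording_id=row["recording_id"],
                start=float(row["start"]),
                end=float(row["end"]),
                species=row["species"],
                score=float(row["score"]),
            )
            for row in reader
        ]
    logger.info("read %d segment scores from %s", len(scores), path)
    return scores


# --------------------------------------------------------------------------
# detection-count CSV
# --------------------------------------------------------------------------

_COUNT_COLUMNS = ["site", "window_start", "species", "count", "moon_illumination"]


def write_detection_counts(records: Sequence[CountRecord], path) -> None:
    """CSV of per-window, per-species counts with the moon covariate.

    Timestamps are written as ISO-8601 with their UTC offset and floats
    at full precision, so the table round-trips losslessly through
    :func:`read_detection_counts`.
    """
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_COUNT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.site_id,
                    pd.Timestamp(r.window_start).isoformat(),
                    r.species,
                    int(r.count),
                    "" if r.moon is None else repr(float(r.moon)),
                ]
            )
    logger.info("wrote %d count records to %s", len(records), path)


def read_detection_counts(path) -> list[CountRecord]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in _COUNT_COLUMNS:
            if col not in (reader.fieldnames or []):
                raise FormatError(f"count table {path} missing column {col!r}")
        records = [
            CountRecord(
                site_id=row["site"],
                window_start=pd.Timestamp(row["window_start"]),
                species=row["species"],
                count=int(row["count"]),
                moon=float(row["moon_illumination"])
                if row["moon_illumination"] != ""
                else None,
            )
            for row in reader
        ]
    logger.info("read %d count records from %s", len(records), path)
    return records


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def load_config(path) -> dict:
    """Load and validate the structured pipeline configuration (YAML).

    Top-level keys: ``sites`` (list of site mappings), ``schedule``,
    ``detector``, ``evaluation``, ``model``, ``simulation``.  Sites are
    parsed into :class:`SiteConfig`; other sections are passed through
    with defaults filled in.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "sites" not in raw or not raw["sites"]:
        raise ConfigError(f"config {path} must define at least one site")
    sites = {}
    for s in raw["sites"]:
        try:
            site = SiteConfig(
                site_id=str(s["site_id"]),
                latitude=float(s["latitude"]),
                longitude=float(s["longitude"]),
                elevation=float(s.get("elevation", 0.0)),
                utc_offset=float(s.get("utc_offset", 0.0)),
                operation_intervals=tuple(
                    (_parse_date(a), _parse_date(b))
                    for a, b in s.get("operation_intervals", [])
                ),
            )
        except KeyError as exc:
            raise ConfigError(f"site entry missing key {exc}") from exc
        sites[site.site_id] = site
    schedule = {
        "night_start_hour": DEFAULT_NIGHT_START_HOUR,
        "night_end_hour": DEFAULT_NIGHT_END_HOUR,
        "window_duration": DEFAULT_WINDOW_DURATION,
    }
    schedule.update(raw.get("schedule", {}))
    detector = {"threshold": 0.95, "segment_length": 0.8,
                "test_advance": 0.2, "field_advance": 0.4}
    detector.update(raw.get("detector", {}))
    evaluation = {"precision_overlap": 0.60, "recall_coverage": 0.50}
    evaluation.update(raw.get("evaluation", {}))
    model = {"family": "zinb"}
    model.update(raw.get("model", {}))
    simulation = {"seed": 0}
    simulation.update(raw.get("simulation", {}))
    return {
        "sites": sites,
        "schedule": schedule,
        "detector": detector,
        "evaluation": evaluation,
        "model": model,
        "simulation": simulation,
    }
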