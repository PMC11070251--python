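"""Summary artifacts: evaluation grid, model comparison, effect table,
and a detections-by-hour-and-night activity grid.

The activity grid places each 10-min recording of one site and species
into a (night, hour-of-night) cell.  Hours are indexed from the start of
the nightly duty cycle (18:00 -> slot 0 by default through 06:00 ->
slot 12).  A night inside the operation schedule with no recording is
*missing* (NaN), encoded distinctly from an observed count of zero —
the distinction matters when recorders were being serviced.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError
from .evalmatch import TIERS, EvalReport
from .io import RecordingWindow
from .zicount import CountRecord, ModelComparison, SpeciesEffect

__all__ = [
    "ActivityGrid",
    "build_activity_grid",
    "summarize_totals",
    "evaluation_frame",
    "comparison_frame",
    "effects_frame",
    "render_activity_grid",
]


@dataclass(frozen=True)
class ActivityGrid:
    """Counts of one site/species indexed by (night, hour-of-night)."""

    site: str
    species: str
    nights: tuple[date, ...]
    hours: tuple[int, ...]               # clock hours in slot order
    counts: np.ndarray                   # shape (n_nights, n_hours); NaN = missing
    night_moon: np.ndarray               # mean covariate per night (NaN if unknown)

    def nightly_totals(self) -> np.ndarray:
        """Sum of observed counts per night (missing cells ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nansum(self.counts, axis=1)

    def total(self) -> int:
        return int(np.nansum(self.counts))


def _night_of(ts: pd.Timestamp, night_start_hour: int) -> date:
    ts = pd.Timestamp(ts)
    d = ts.date()
    return d if ts.hour >= night_start_hour else d - timedelta(days=1)


def build_activity_grid(
    records: Sequence[CountRecord],
    schedule: Sequence[RecordingWindow],
    site: str | None = None,
    species: str | None = None,
    night_start_hour: int = 18,
) -> ActivityGrid:
    """Arrange one site/species' counts on the schedule's night-hour grid.

    Cells covered by the schedule but lacking a record are NaN
    (recorder down); a record whose window is not in the schedule raises
    :class:`PlacementError`.
    """
    records = [
        r
        for r in records
        if (site is None or r.site_id == site)
        and (species is None or r.species == species)
    ]
    sites = {r.site_id for r in records}
    sps = {r.species for r in records}
    if len(sites) > 1 or len(sps) > 1:
        raise PlacementError(
            "activity grid needs records from a single site and species; "
            f"got sites {sorted(sites)}, species {sorted(sps)}"
        )
    if site is None:
        if sites:
            site = next(iter(sites))
        else:
            sched_sites = {w.site_id for w in schedule}
            if len(sched_sites) != 1:
                raise PlacementError(
                    "site is ambiguous: pass one explicitly"
                )
            site = next(iter(sched_sites))
    species = species or (next(iter(sps)) if sps else "")

    sched = [w for w in schedule if w.site_id == site]
    slot_keys = {}
    hours_order: list[int] = []
    nights_set = set()
    for w in sched:
        ts = pd.Timestamp(w.start)
        night = _night_of(ts, night_start_hour)
        nights_set.add(night)
        if ts.hour not in hours_order:
            hours_order.append(ts.hour)
        slot_keys[(night, ts.hour)] = None
    nights = tuple(sorted(nights_set))
    hours = tuple(hours_order)
    night_ix = {n: i for i, n in enumerate(nights)}
    hour_ix = {h: i for i, h in enumerate(hours)}

    counts = np.full((len(nights), len(hours)), np.nan)
    moon_sum = np.zeros(len(nights))
    moon_n = np.zeros(len(nights))
    for r in records:
        ts = pd.Timestamp(r.window_start)
        night = _night_of(ts, night_start_hour)
        key = (night, ts.hour)
        if key not in slot_keys:
            raise PlacementError(
                f"record at {ts} does not match any scheduled window of {site}"
            )
        counts[night_ix[night], hour_ix[ts.hour]] = r.count
        if r.moon is not None:
            moon_sum[night_ix[night]] += r.moon
            moon_n[night_ix[night]] += 1
    with np.errstate(invalid="ignore"):
        night_moon = np.where(moon_n > 0, moon_sum / np.maximum(moon_n, 1), np.nan)
    return ActivityGrid(site, species, nights, hours, counts, night_moon)


def summarize_totals(
    records: Sequence[CountRecord],
) -> tuple[dict[str, int], int]:
    """Aggregate detections per species and the grand total.

    The grand total always equals the sum of per-species totals exactly
    (both are plain integer sums over the same records).
    """
    totals: dict[str, int] = {}
    for r in records:
        totals[r.species] = totals.get(r.species, 0) + int(r.count)
    return totals, sum(totals.values())


def evaluation_frame(reports: Iterable[EvalReport]) -> pd.DataFrame:
    """Species-by-tier precision/recall grid (the evaluation-table shape)."""
    rows = {}
    for r in reports:
        rows.setdefault(r.species, {})[f"{r.tier}:precision"] = r.precision
        rows[r.species][f"{r.tier}:recall"] = r.recall
        rows[r.species][f"{r.tier}:n_annotations"] = r.n_annotations
    cols = [f"{t}:{m}" for t in TIERS for m in ("precision", "recall", "n_annotations")]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    df.index.name = "species"
    return df.sort_index()


def comparison_frame(comparison: ModelComparison) -> pd.DataFrame:
    """Model-comparison table: AIC, dAIC, d.f. and Akaike weight."""
    return comparison.to_frame()


def effects_frame(
    effects: Sequence[SpeciesEffect],
    records: Sequence[CountRecord] | None = None,
) -> pd.DataFrame:
    """Per-species effect table: totals, new/full predictions, change, R^2."""
    totals = summarize_totals(records)[0] if records is not None else {}
    return pd.DataFrame(
        [
            {
                "species": e.species,
                "total_detections": totals.get(e.species),
                "new_moon": e.pred_new_moon,
                "full_moon": e.pred_full_moon,
                "delta": e.delta,
                "percent_change": e.percent_change,
                "r2": e.pseudo_r2,
            }
            for e in effects
        ]
    )


def render_activity_grid(grid: ActivityGrid, path) -> None:
    """Render the grid as a heat map (cosmetic; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_moon, ax) = plt.subplots(
        2, 1, figsize=(max(6, len(grid.nights) / 8), 4),
        height_ratios=[1, 10], sharex=True,
    )
    ax_moon.imshow(
        grid.night_moon[None, :], aspect="auto", cmap="gray", vmin=0, vmax=1
    )
    ax_moon.set_yticks([])
    masked = np.ma.masked_invalid(grid.counts.T)
    cmap = plt.get_cmap("Blues").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, aspect="auto", cmap=cmap, origin="upper")
    ax.set_yticks(range(len(grid.hours)), [f"{h:02d}:00" for h in grid.hours])
    ax.set_xlabel("night")
    ax.set_title(f"{grid.species} at {grid.site}")
    fig.colorbar(im, ax=ax, label="detections / 10 min")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
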