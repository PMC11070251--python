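"""Synthetic inputs with the statistical structure the analysis assumes.

Two levels of simulation are provided:

* **count level** — per-window, per-species detection counts drawn from
  a zero-inflated negative-binomial generalized linear mixed model with
  known parameters, for fitting and parameter-recovery work;
* **event level** — soundscapes of call intervals plus recognizer
  segment scores, including *faint* true calls that a human annotator
  misses but the recognizer finds (the mechanism behind the tiered test
  sets), and a false-positive process.

The default truth emulates a multi-year tropical-forest katydid study:
eight species at four sites, new-moon calling rates spanning roughly
0.5-17.6 detections per 10-min window, species-specific log-linear
moonlight effects within about +/-35% between new and full moon, excess
zeros and strong overdispersion, and random intercepts for time block,
site and their species crossings.  No acoustic realism is attempted:
there are no waveforms, only call intervals and scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evalmatch import Annotation, label_detections_for_precision
from .io import RecordingWindow, SiteConfig
from .moonpred import attach_moon
from .segdetect import DetectionEvent, SegmentScore, segment_grid
from .zicount import CountRecord, default_time_block

__all__ = [
    "DetectorEmulation",
    "SimTruth",
    "SoundscapeSample",
    "default_truth",
    "simulate_counts",
    "simulate_soundscape",
    "review_detections",
]


@dataclass(frozen=True)
class DetectorEmulation:
    """How the event-level simulator emulates calls and a recognizer."""

    call_rate_per_window: float = 6.0     # expected true calls / 10 min
    call_duration_range: tuple[float, float] = (0.6, 1.6)  # seconds
    faint_call_fraction: float = 0.2      # true calls absent from human set
    false_positive_rate: float = 0.5      # expected spurious events / window
    unable_fraction: float = 0.3          # reviewer gives up on this share of FPs
    hit_score_beta: tuple[float, float] = (40.0, 1.0)   # scores over calls
    background_score_beta: tuple[float, float] = (1.0, 30.0)
    segment_length: float = 0.8
    segment_advance: float = 0.2


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters for the count-level simulator.

    ``log_rates`` are species intercepts for the conditional mean (log
    detections per window at covariate 0); ``moon_slopes`` multiply the
    rescaled moonlight covariate on the log scale.  ``theta=None``
    selects Poisson counts.  Variances are on the log (latent) scale.
    """

    species: tuple[str, ...]
    log_rates: Mapping[str, float]
    moon_slopes: Mapping[str, float]
    zi_prob: float = 0.25
    theta: float | None = 0.8
    variance_components: Mapping[str, float] = field(
        default_factory=lambda: {
            "time_block": 0.15,
            "site": 0.15,
            "species_site": 0.20,
            "species_time_block": 0.20,
        }
    )
    detector: DetectorEmulation = field(default_factory=DetectorEmulation)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zi_prob < 1.0:
            raise ValueError("zi_prob must be in [0, 1)")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive (or None for Poisson)")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variances must be non-negative")


#: new-moon rates (detections / 10 min) and new-to-full percent changes
#: typical of a multi-species forest-katydid soundscape study
_DEFAULT_RATES = {
    "Acantheremus major": (7.0, 21.1),
    "Anaulacomera furcata": (4.4, 0.0),
    "Anaulacomera spatulata": (0.5, 22.5),
    "Erioloides longinoi": (0.7, -18.6),
    "Euceraia insignis": (0.9, 21.7),
    "Montezumina bradleyi": (0.56, -35.4),
    "Pristonotus tuberosus": (17.6, -3.5),
    "Thamnobates subfalcata": (12.9, -6.7),
}


def default_truth(seed: int = 0, zi_prob: float = 0.25,
                  theta: float | None = 0.8) -> SimTruth:
    """Eight-species truth at field-realistic magnitudes.

    Intercepts are chosen so the *expected* detections per window at new
    moon (after zero-inflation thinning) match the target rates; slopes
    are ``ln(1 - pct/100)`` so the new-to-full percent change matches.
    """
    species = tuple(_DEFAULT_RATES)
    log_rates = {
        sp: math.log(rate / (1.0 - zi_prob))
        for sp, (rate, _) in _DEFAULT_RATES.items()
    }
    slopes = {
        sp: math.log1p(-pct / 100.0) for sp, (_, pct) in _DEFAULT_RATES.items()
    }
    return SimTruth(
        species=species,
        log_rates=log_rates,
        moon_slopes=slopes,
        zi_prob=zi_prob,
        theta=theta,
        seed=seed,
    )


def _species_stream(master_seed: int, tag: int, species_index: int) -> np.random.Generator:
    # independent, reproducible substream per (purpose, species)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(tag, species_index))
    )


def simulate_counts(
    truth: SimTruth,
    schedule: Sequence[RecordingWindow],
    sites: Mapping[str, SiteConfig],
    seed: int | None = None,
) -> tuple[list[CountRecord], SimTruth]:
    """Draw per-window, per-species counts from the generating model.

    The moonlight covariate is computed from the window midpoints and
    min-max rescaled to [0, 1]; random effects are drawn once per group
    level; each species then receives its own reproducible random
    substream, so output is byte-identical for a fixed seed.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    master = truth.seed if seed is None else seed
    truth = replace(truth, seed=master)

    windows = list(schedule)
    base = [
        CountRecord(
            site_id=w.site_id,
            window_start=pd.Timestamp(w.start),
            species="_",
            count=0,
            time_block=default_time_block(w.start),
        )
        for w in windows
    ]
    base = attach_moon(base, sites, passthrough=False)
    moon = np.array([r.moon for r in base])
    tb = [r.time_block for r in base]
    site_ids = [r.site_id for r in base]

    # group levels and their random intercepts
    tb_levels = sorted(set(tb))
    site_levels = sorted(sites)
    re_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=master, spawn_key=(0,))
    )
    v = truth.variance_components

    def _draw(levels, var):
        sd = math.sqrt(var) if var > 0 else 0.0
        return dict(zip(levels, re_rng.normal(0.0, sd, size=len(levels))))

    u_tb = _draw(tb_levels, v.get("time_block", 0.0))
    u_site = _draw(site_levels, v.get("site", 0.0))
    u_ss = _draw(
        [f"{sp}|{s}" for sp in truth.species for s in site_levels],
        v.get("species_site", 0.0),
    )
    u_st = _draw(
        [f"{sp}|{t}" for sp in truth.species for t in tb_levels],
        v.get("species_time_block", 0.0),
    )

    tb_eff = np.array([u_tb[t] for t in tb])
    site_eff = np.array([u_site[s] for s in site_ids])

    records: list[CountRecord] = []
    for j, sp in enumerate(truth.species):
        rng = _species_stream(master, 1, j)
        eta = (
            truth.log_rates[sp]
            + truth.moon_slopes[sp] * moon
            + tb_eff
            + site_eff
            + np.array([u_ss[f"{sp}|{s}"] for s in site_ids])
            + np.array([u_st[f"{sp}|{t}"] for t in tb])
        )
        mu = np.exp(eta)
        if truth.theta is None:
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(truth.theta, mu / truth.theta)
            counts = rng.poisson(lam)
        if truth.zi_prob > 0:
            counts = np.where(rng.random(len(mu)) < truth.zi_prob, 0, counts)
        records.extend(
            CountRecord(
                site_id=site_ids[i],
                window_start=base[i].window_start,
                species=sp,
                count=int(counts[i]),
                moon=float(moon[i]),
                time_block=tb[i],
            )
            for i in range(len(windows))
        )
    return records, truth


@dataclass(frozen=True)
class SoundscapeSample:
    """One simulated window: reference annotations, faint calls, scores."""

    base_annotations: list[Annotation]
    faint_calls: list[Annotation]
    segment_scores: list[SegmentScore]

    @property
    def all_true_calls(self) -> list[Annotation]:
        return self.base_annotations + self.faint_calls


def simulate_soundscape(
    truth: SimTruth,
    window: RecordingWindow,
    species: str,
    seed: int | None = None,
) -> SoundscapeSample:
    """Simulate true calls and recognizer scores for one window/species.

    Call onsets follow a Poisson process; a configurable fraction of
    calls is *faint*: real (and scored highly by the recognizer) but
    excluded from the base human annotation set.  Segments overlapping a
    call draw scores from the hit distribution, others from the
    background distribution, and a Poisson number of false-positive
    segment runs is injected away from any true call.
    """
    if window.duration <= 0:
        raise ValueError("window duration must be positive")
    det = truth.detector
    j = truth.species.index(species) if species in truth.species else 0
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=truth.seed if seed is None else seed,
            spawn_key=(2, j, abs(hash(window.recording_id)) % 2**31),
        )
    )
    rec_id = window.recording_id
    dur = float(window.duration)

    n_calls = rng.poisson(det.call_rate_per_window)
    lo, hi = det.call_duration_range
    calls = []
    for _ in range(n_calls):
        length = rng.uniform(lo, hi)
        start = rng.uniform(0.0, max(dur - length, 0.0))
        faint = rng.random() < det.faint_call_fraction
        calls.append((start, start + length, faint))
    calls.sort()

    base = [
        Annotation(rec_id, s, e, species, origin="human")
        for s, e, faint in calls
        if not faint
    ]
    faint_calls = [
        Annotation(rec_id, s, e, species, origin="human")
        for s, e, faint in calls
        if faint
    ]

    grid = segment_grid(dur, det.segment_length, det.segment_advance)
    starts = np.array([g[0] for g in grid])
    ends = np.array([g[1] for g in grid])
    seg_len = det.segment_length

    over_call = np.zeros(len(grid), dtype=bool)
    for s, e, _ in calls:
        overlap = np.minimum(ends, e) - np.maximum(starts, s)
        over_call |= overlap >= 0.5 * seg_len

    a_hit, b_hit = det.hit_score_beta
    a_bg, b_bg = det.background_score_beta
    scores = np.where(
        over_call,
        rng.beta(a_hit, b_hit, len(grid)),
        rng.beta(a_bg, b_bg, len(grid)),
    )

    # false positives: short runs of hit-level scores away from true calls
    n_fp = rng.poisson(det.false_positive_rate)
    free = np.flatnonzero(~over_call)
    for _ in range(n_fp):
        if len(free) < 4:
            break
        k = rng.integers(0, len(free) - 2)
        run = free[k : k + rng.integers(2, 4)]
        run = run[np.diff(np.concatenate([[run[0] - 1], run])) == 1]
        scores[run] = rng.beta(a_hit, b_hit, len(run))

    segment_scores = [
        SegmentScore(rec_id, float(s), float(e), species, float(sc))
        for (s, e), sc in zip(grid, scores)
    ]
    return SoundscapeSample(base, faint_calls, segment_scores)


def review_detections(
    events: Sequence[DetectionEvent],
    sample: SoundscapeSample,
    seed: int = 0,
    unable_fraction: float | None = None,
) -> list[DetectionEvent]:
    """Emulate human review of apparent false positives.

    Events that are true positives against the base annotations are left
    unreviewed (a reviewer never sees them).  Events matching a faint
    true call are confirmed; of the remainder, a configurable fraction
    cannot be confirmed or rejected ("unable to reject") and the rest
    are rejected.
    """
    if unable_fraction is None:
        unable_fraction = 0.3
    rng = np.random.default_rng(seed)
    tp_base = label_detections_for_precision(events, sample.base_annotations)
    tp_faint = label_detections_for_precision(events, sample.faint_calls)
    reviewed = []
    for ev, in_base, in_faint in zip(events, tp_base, tp_faint):
        if in_base:
            status = "unreviewed"
        elif in_faint:
            status = "confirmed"
        elif rng.random() < unable_fraction:
            status = "unable_to_reject"
        else:
            status = "rejected"
        reviewed.append(replace(ev, review_status=status))
    return reviewed
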