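"""Synthetic developmental-song generator with known ground truth.

The generator emulates the structure of intermittent song-development
recordings: one bird recorded about every 4 days from about day 40
post-hatch, a few recording files per day, thousands of notes per day.  Each
day's inter-onset intervals are drawn i.i.d. from a mixture of Gaussian
"bands" whose means, jitter standard deviations and weights follow per-band
day schedules; note onsets accumulate as running sums within each recording
file, durations are drawn per note and capped below the following interval so
silent gaps stay non-negative, and wall-clock timestamps spread uniformly
across the recording day.

Band lifecycles are planted explicitly: a *founder* band present from the
start, *branching* bands that split off a parent at a stated distance and
drift away, and *de-novo* bands that appear far from any precursor.  Jitter
schedules anneal (broad early, tight late), so the divergence toward the
final day decays smoothly.  All the planted structure is emitted as a
:class:`GroundTruth` object, making every downstream analysis testable by
parameter recovery.  The i.i.d. draw is sufficient because all downstream
analyses are distributional; no within-bout sequence model is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigError
from .notes_io import DevelopmentDataset, NoteEvent, Recording
from .proficiency import js_divergence
from .rhythm import DEFAULT_BIN_WIDTH, DEFAULT_RANGE

__all__ = [
    "Schedule",
    "BandSpec",
    "SimConfig",
    "TrueEvent",
    "GroundTruth",
    "simulate_development",
    "preset_paperlike",
    "simulate_cohort",
]


@dataclass(frozen=True)
class Schedule:
    """Piecewise-linear day schedule; constant outside the anchor range."""

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        days = [a[0] for a in self.anchors]
        if not self.anchors or days != sorted(days):
            raise ConfigError("schedule anchors must be ascending in day")

    def at(self, day: float) -> float:
        xs = [a[0] for a in self.anchors]
        ys = [a[1] for a in self.anchors]
        return float(np.interp(day, xs, ys))

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls(((0.0, value),))


@dataclass(frozen=True)
class BandSpec:
    """One planted band and its day schedules.

    ``mode`` is ``founder`` (present from the first recording day),
    ``branching`` (splits off ``parent_track`` at ``birth_day``) or
    ``denovo`` (appears without a precursor).
    """

    track_id: str
    birth_day: int
    mode: str  # founder | branching | denovo
    position: Schedule
    sd: Schedule
    weight: Schedule
    parent_track: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("founder", "branching", "denovo"):
            raise ConfigError(f"unknown band mode {self.mode!r}")
        if self.mode == "branching" and self.parent_track is None:
            raise ConfigError(f"branching band {self.track_id} needs parent_track")


@dataclass
class SimConfig:
    """Study conditions for one simulated bird.

    Defaults emulate the recording design the method targets: recordings
    every 4 days from day 40 to day 148, 8000 notes per day split over 4
    recording files.  Interval draws are clipped to [20, 350] ms; durations
    are Gaussian (mean 40 ms, sd 10 ms) clipped to [15 ms, following interval
    - 2 ms] so every note survives the 15/350 ms noise filter and every gap
    is positive.  ``weight_step``, if set, switches the mixture weights at a
    wall-clock hour of one day: (day, hour, {track_id: weight}).
    """

    bird_id: str = "synthetic-bird"
    recording_days: tuple[int, ...] = tuple(range(40, 152, 4))
    notes_per_day: int = 8000
    recordings_per_day: int = 4
    bands: tuple[BandSpec, ...] = ()
    duration_mean: float = 40.0
    duration_sd: float = 10.0
    ioi_clip: tuple[float, float] = (20.0, 350.0)
    hour_range: tuple[float, float] = (0.0, 24.0)
    weight_step: tuple[int, float, Mapping[str, float]] | None = None
    seed: int = 0


@dataclass(frozen=True)
class TrueEvent:
    """A planted emergence event (recovery-test oracle)."""

    track_id: str
    day: int  # first recording day the band is active
    position: float  # planted mean at that day (ms)
    stem_track: str
    stem_position: float  # stem's planted mean on the prior recording day
    distance: float
    cls: str  # branching | other


@dataclass
class GroundTruth:
    """Planted structure behind a simulated dataset."""

    band_positions: dict[int, list[tuple[str, float, float, float]]]
    #: day -> [(track_id, position_ms, weight, sd_ms)]
    events: list[TrueEvent]
    js_reference: dict[int, float]
    #: analytic JS of each day's planted mixture against the final day

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "band_positions": {
                    str(day): [
                        {"track_id": t, "position": p, "weight": w, "sd": s}
                        for t, p, w, s in bands
                    ]
                    for day, bands in self.band_positions.items()
                },
                "events": [e.__dict__ for e in self.events],
                "js_reference": {str(d): v for d, v in self.js_reference.items()},
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _active(cfg: SimConfig, day: int) -> list[BandSpec]:
    return [b for b in cfg.bands if b.birth_day <= day]


def _weights(bands: Sequence[BandSpec], day: int) -> np.ndarray:
    w = np.array([b.weight.at(day) for b in bands], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigError(f"day {day}: band weights not normalizable ({w})")
    return w / w.sum()


def _mixture_bin_probs(
    bands: Sequence[tuple[str, float, float, float]],
    value_range: tuple[float, float] = DEFAULT_RANGE,
    width: float = DEFAULT_BIN_WIDTH,
) -> np.ndarray:
    """Analytic binned probabilities of a planted Gaussian band mixture."""
    lo, hi = value_range
    edges = lo + width * np.arange(int(round((hi - lo) / width)) + 1)
    probs = np.zeros(len(edges) - 1)
    for _, mu, w, sd in bands:
        cdf = norm.cdf(edges, loc=mu, scale=sd)
        probs += w * np.diff(cdf)
    total = probs.sum()
    if total <= 0:
        raise ConfigError("planted mixture has no mass inside the analysis range")
    return probs / total


def simulate_development(cfg: SimConfig) -> tuple[DevelopmentDataset, GroundTruth]:
    """Draw a full developmental dataset plus its ground truth.

    Deterministic for a fixed ``cfg.seed`` (byte-identical note tables).
    """
    if not cfg.bands:
        raise ConfigError("config has no bands")
    rng = np.random.default_rng(cfg.seed)
    days = sorted(cfg.recording_days)
    for day in days:
        if not _active(cfg, day):
            raise ConfigError(f"no band active on recording day {day}")

    recordings: list[Recording] = []
    truth_positions: dict[int, list[tuple[str, float, float, float]]] = {}
    rec_id = 0
    notes_per_rec = cfg.notes_per_day // cfg.recordings_per_day
    if notes_per_rec < 2:
        raise ConfigError("fewer than 2 notes per recording")
    h_lo, h_hi = cfg.hour_range

    for day in days:
        bands = _active(cfg, day)
        w = _weights(bands, day)
        mu = np.array([b.position.at(day) for b in bands])
        sd = np.array([b.sd.at(day) for b in bands])
        truth_positions[day] = [
            (b.track_id, float(m), float(wi), float(s))
            for b, m, wi, s in zip(bands, mu, w, sd)
        ]
        stepped = cfg.weight_step is not None and cfg.weight_step[0] == day
        if stepped:
            _, step_hour, step_map = cfg.weight_step
            w2 = np.array([step_map.get(b.track_id, 0.0) for b in bands], dtype=float)
            if np.any(w2 < 0) or w2.sum() <= 0:
                raise ConfigError("weight_step weights not normalizable")
            w2 = w2 / w2.sum()
        for r in range(cfg.recordings_per_day):
            rec_id += 1
            frac0, frac1 = r / cfg.recordings_per_day, (r + 1) / cfg.recordings_per_day
            rh_lo = h_lo + (h_hi - h_lo) * frac0
            rh_hi = h_lo + (h_hi - h_lo) * frac1
            m = notes_per_rec
            hours = rh_lo + (rh_hi - rh_lo) * (np.arange(m) + 0.5) / m
            n_ioi = m - 1
            comp = rng.choice(len(bands), size=n_ioi, p=w)
            if stepped:
                comp_post = rng.choice(len(bands), size=n_ioi, p=w2)
                comp = np.where(hours[:-1] < step_hour, comp, comp_post)
            iois = rng.normal(mu[comp], sd[comp])
            np.clip(iois, *cfg.ioi_clip, out=iois)
            onsets = np.concatenate(([0.0], np.cumsum(iois)))
            durations = rng.normal(cfg.duration_mean, cfg.duration_sd, size=m)
            caps = np.concatenate((iois - 2.0, [350.0]))
            durations = np.clip(durations, 15.0, caps)
            events = [
                NoteEvent(
                    recording_id=rec_id,
                    day=day,
                    onset=float(onsets[i]),
                    duration=float(durations[i]),
                    timestamp=float(hours[i]),
                )
                for i in range(m)
            ]
            recordings.append(Recording(rec_id, day, events))

    events = _planted_events(cfg, days)
    final = days[-1]
    p_final = _mixture_bin_probs(truth_positions[final])
    js_ref = {
        day: js_divergence(p_final, _mixture_bin_probs(truth_positions[day])).value
        for day in days
    }
    ds = DevelopmentDataset(bird_id=cfg.bird_id, recordings=recordings)
    return ds, GroundTruth(truth_positions, events, js_ref)


def _planted_events(cfg: SimConfig, days: Sequence[int]) -> list[TrueEvent]:
    by_id = {b.track_id: b for b in cfg.bands}
    out: list[TrueEvent] = []
    for band in cfg.bands:
        if band.mode == "founder":
            continue
        later = [d for d in days if d >= band.birth_day]
        earlier = [d for d in days if d < band.birth_day]
        if not later or not earlier:
            raise ConfigError(
                f"band {band.track_id}: birth day {band.birth_day} leaves no "
                "prior recording day for a stem"
            )
        day0, prev = later[0], earlier[-1]
        pos0 = band.position.at(day0)
        if band.mode == "branching":
            stem = by_id[band.parent_track]
        else:
            others = [b for b in _active(cfg, prev) if b.track_id != band.track_id]
            stem = min(others, key=lambda b: abs(b.position.at(prev) - pos0))
        stem_pos = stem.position.at(prev)
        out.append(
            TrueEvent(
                track_id=band.track_id,
                day=day0,
                position=float(pos0),
                stem_track=stem.track_id,
                stem_position=float(stem_pos),
                distance=float(abs(pos0 - stem_pos)),
                cls="branching" if band.mode == "branching" else "other",
            )
        )
    return out


def _clipped_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def preset_paperlike(
    rng: np.random.Generator | None = None,
    bird_id: str = "synthetic-bird",
    notes_per_day: int = 8000,
    seed: int = 0,
    flatten_day: int = 90,
) -> SimConfig:
    """A paper-like developmental scenario with planted structure.

    A broadband founder (kernel of the adult rhythm, jitter annealing
    45 -> 8 ms while drifting in from long intervals) develops into five
    terminal bands before day 80 through three branching events (days 56, 64
    and 68, planted stem distances drawn near 25 ms, children drifting
    outward after birth) and one de-novo emergence (day 60, near 78 ms from
    the stem).  Branching children are planted relative to the stem's
    position on the *prior* recording day, so the planted stem distance is
    exactly the drawn value.  All schedules are constant from
    ``flatten_day`` on (planted crystallization): the divergence toward the
    final day decays roughly exponentially to a sampling floor, then
    flattens.

    With ``rng`` given, the planted distances and the terminal founder
    position vary per draw; without it the central scenario is returned.
    ``seed`` seeds the note draws of the resulting config.
    """
    draw = rng is not None
    p0 = _clipped_normal(rng, 175.0, 6.0, 160.0, 190.0) if draw else 175.0
    d1 = _clipped_normal(rng, 25.0, 8.0, 15.0, 42.0) if draw else 25.0
    d2 = _clipped_normal(rng, 25.0, 8.0, 15.0, 42.0) if draw else 25.0
    d4 = _clipped_normal(rng, 25.0, 8.0, 15.0, 42.0) if draw else 25.0
    d3 = _clipped_normal(rng, 78.0, 10.0, 65.0, 105.0) if draw else 78.0
    b1, b3, b4, b2 = 56, 60, 64, 68

    fd = float(flatten_day)
    founder = BandSpec(
        track_id="T0",
        birth_day=40,
        mode="founder",
        position=Schedule(((40, p0 + 75.0), (44, p0 + 55.0), (48, p0 + 33.0),
                           (52, p0 + 7.0), (56, p0), (fd, p0))),
        sd=Schedule(((40, 45.0), (44, 25.0), (48, 20.0), (52, 14.0),
                     (56, 11.0), (64, 9.0), (fd, 8.0))),
        weight=Schedule(((40, 1.0), (60, 0.6), (70, 0.5), (fd, 0.35))),
    )
    t1 = BandSpec(
        track_id="T1",
        birth_day=b1,
        mode="branching",
        parent_track="T0",
        position=Schedule(((b1, founder.position.at(b1 - 4) - d1),
                           (64, p0 - 33.0), (80, p0 - 45.0), (fd, p0 - 47.0))),
        sd=Schedule(((b1, 8.0), (76, 9.0), (fd, 7.0))),
        weight=Schedule(((b1, 0.15), (60, 0.24), (fd, 0.25))),
    )
    t3 = BandSpec(
        track_id="T3",
        birth_day=b3,
        mode="denovo",
        position=Schedule(((b3, p0 + d3), (fd, p0 + 80.0))),
        sd=Schedule(((b3, 10.0), (fd, 8.0))),
        weight=Schedule(((b3, 0.10), (64, 0.16), (fd, 0.16))),
    )
    t4 = BandSpec(
        track_id="T4",
        birth_day=b4,
        mode="branching",
        parent_track="T0",
        position=Schedule(((b4, founder.position.at(b4 - 4) + d4),
                           (72, p0 + 32.0), (80, p0 + 37.0), (fd, p0 + 38.0))),
        sd=Schedule(((b4, 8.0), (76, 9.0), (fd, 7.0))),
        weight=Schedule(((b4, 0.15), (68, 0.22), (fd, 0.2))),
    )
    t2 = BandSpec(
        track_id="T2",
        birth_day=b2,
        mode="branching",
        parent_track="T1",
        position=Schedule(((b2, t1.position.at(b2 - 4) - d2),
                           (76, p0 - 70.0), (84, p0 - 78.0), (fd, p0 - 80.0))),
        sd=Schedule(((b2, 8.0), (80, 9.0), (fd, 7.0))),
        weight=Schedule(((b2, 0.14), (72, 0.18), (fd, 0.18))),
    )
    return SimConfig(
        bird_id=bird_id,
        notes_per_day=notes_per_day,
        bands=(founder, t1, t2, t3, t4),
        seed=seed,
    )


def simulate_cohort(
    n_birds: int = 12,
    seed: int = 0,
    notes_per_day: int = 8000,
) -> list[tuple[DevelopmentDataset, GroundTruth]]:
    """A cohort of paper-like birds with independently drawn scenarios."""
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_birds):
        cfg = preset_paperlike(
            rng=master,
            bird_id=f"synthetic-bird-{i:02d}",
            notes_per_day=notes_per_day,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        out.append(simulate_development(cfg))
    return out
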