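"""End-to-end per-bird analysis: ties the modules into one pipeline.

`analyze_bird` runs the standard sequence — duration noise filter, per-day
smoothed densities and band detection, band tracking, stem assignment and
emergence classification, JS trajectory — with every threshold exposed and
defaulting to the package-wide values.  `match_planted_events` aligns
detected emergence events with a simulator's planted ground truth for
parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import bands as bands_mod
from .bands import (
    DEFAULT_BANDWIDTH,
    DEFAULT_DAY_LIMIT,
    DEFAULT_DISTANCE_CAP,
    DEFAULT_LINK_THRESHOLD,
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_VALLEY_RATIO,
    Band,
    BandTrack,
    DensityCurve,
    EmergenceEvent,
)
from .notes_io import (
    NOISE_MAX_DURATION,
    NOISE_MIN_DURATION,
    DevelopmentDataset,
    filter_notes,
)
from .proficiency import Trajectory, js_trajectory
from .synthetic import TrueEvent

#: ground-truth matching tolerances: a branching child planted a few ms from
#: its stem is unresolvable until it drifts out, so first detection can lag
#: the planted birth by up to ~3 recording sessions.
MATCH_DAY_TOL = 12.0
MATCH_POS_TOL = 25.0


@dataclass
class BirdAnalysis:
    """Everything the pipeline derives for one bird."""

    bird_id: str
    n_events: int
    n_removed_by_filter: int
    per_day_bands: dict[int, list[Band]]
    curves: dict[int, DensityCurve]
    tracks: list[BandTrack]
    events: list[EmergenceEvent]
    trajectory: Trajectory

    def bands_table(self) -> pd.DataFrame:
        rows = [
            {
                "bird": self.bird_id, "day": day, "position_ms": b.position,
                "height": b.height, "prominence": b.prominence,
            }
            for day in sorted(self.per_day_bands)
            for b in self.per_day_bands[day]
        ]
        return pd.DataFrame(
            rows, columns=["bird", "day", "position_ms", "height", "prominence"]
        )

    def events_table(self) -> pd.DataFrame:
        rows = [
            {
                "bird": self.bird_id, "day": e.day, "new_ms": e.new_position,
                "stem_ms": e.stem_position, "distance_ms": e.distance,
                "class": e.cls,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["bird", "day", "new_ms", "stem_ms", "distance_ms", "class"]
        )


def analyze_bird(
    ds: DevelopmentDataset,
    min_dur: float = NOISE_MIN_DURATION,
    max_dur: float = NOISE_MAX_DURATION,
    bandwidth: float | str = DEFAULT_BANDWIDTH,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    link_threshold: float = DEFAULT_LINK_THRESHOLD,
    valley_ratio: float = DEFAULT_VALLEY_RATIO,
    distance_cap: float = DEFAULT_DISTANCE_CAP,
    day_limit: int | None = DEFAULT_DAY_LIMIT,
) -> BirdAnalysis:
    """Run the full single-bird pipeline with the given thresholds."""
    filtered, removed = filter_notes(ds, min_dur, max_dur)
    per_day, curves = bands_mod.bands_per_day(
        filtered, bandwidth=bandwidth, min_prominence=min_prominence
    )
    tracks, events = bands_mod.track_bands(per_day, link_threshold)
    days = sorted(curves)
    enriched: list[EmergenceEvent] = []
    for ev in events:
        prior = days[days.index(ev.day) - 1]
        ev = bands_mod.assign_stem(ev, curves[prior], min_prominence)
        ev.cls = bands_mod.classify_emergence(
            ev, curves, valley_ratio, distance_cap, day_limit
        )
        enriched.append(ev)
    trajectory = js_trajectory(filtered)
    return BirdAnalysis(
        bird_id=ds.bird_id,
        n_events=filtered.n_events,
        n_removed_by_filter=removed,
        per_day_bands=per_day,
        curves=curves,
        tracks=tracks,
        events=enriched,
        trajectory=trajectory,
    )


def match_planted_events(
    detected: Sequence[EmergenceEvent],
    planted: Sequence[TrueEvent],
    day_tol: float = MATCH_DAY_TOL,
    pos_tol: float = MATCH_POS_TOL,
) -> list[tuple[TrueEvent, EmergenceEvent | None]]:
    """Pair each planted event with its best-matching detected event.

    A detected event is a candidate when it lies within ``day_tol`` days and
    ``pos_tol`` ms of the planted birth; each detected event is used at most
    once, closest (day difference, then position difference) first.  Planted
    events with no candidate pair with None.
    """
    pairs: list[tuple[TrueEvent, EmergenceEvent | None]] = []
    used: set[int] = set()
    for te in planted:
        best: tuple[tuple[float, float], int] | None = None
        for i, de in enumerate(detected):
            if i in used:
                continue
            dday = abs(de.day - te.day)
            dpos = abs(de.new_position - te.position)
            if dday <= day_tol and dpos <= pos_tol:
                score = (dday, dpos)
                if best is None or score < best[0]:
                    best = (score, i)
        if best is None:
            pairs.append((te, None))
        else:
            used.add(best[1])
            pairs.append((te, detected[best[1]]))
    return pairs
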