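from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhythmscape import DevelopmentDataset, NoteEvent, Recording

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_recording(
    onsets,
    durations=None,
    recording_id: int = 1,
    day: int = 50,
    hours=None,
) -> Recording:
    """Build a recording from onset (and optional duration/hour) lists."""
    onsets = list(onsets)
    if durations is None:
        durations = [10.0] * len(onsets)
    if hours is None:
        hours = [None] * len(onsets)
    events = [
        NoteEvent(recording_id, day, float(o), float(d), h)
        for o, d, h in zip(onsets, durations, hours)
    ]
    return Recording(recording_id, day, events)


def make_dataset(day_onsets: dict[int, list[list[float]]], bird_id="b1", **kw):
    """day -> list of per-recording onset lists."""
    recordings = []
    rid = 0
    for day in sorted(day_onsets):
        for onsets in day_onsets[day]:
            rid += 1
            recordings.append(make_recording(onsets, recording_id=rid, day=day, **kw))
    return DevelopmentDataset(bird_id=bird_id, recordings=recordings)


def dataset_from_iois(day_iois: dict[int, np.ndarray], bird_id="b1") -> DevelopmentDataset:
    """One recording per day whose consecutive IOIs are the given values."""
    recordings = []
    for rid, day in enumerate(sorted(day_iois), start=1):
        onsets = np.concatenate(([0.0], np.cumsum(np.asarray(day_iois[day], float))))
        durations = np.full(onsets.size, 10.0)
        events = [
            NoteEvent(rid, day, float(o), float(d))
            for o, d in zip(onsets, durations)
        ]
        recordings.append(Recording(rid, day, events))
    return DevelopmentDataset(bird_id=bird_id, recordings=recordings)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
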