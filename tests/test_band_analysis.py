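from __future__ import annotations

import numpy as np
import pytest

from rhythmscape import (
    ParameterError,
    SmoothingError,
    assign_stem,
    band_usage_rate,
    classify_emergence,
    count_bands_by_decade,
    daily_distribution,
    detect_bands,
    emergence_statistics,
    smooth_distribution,
    track_bands,
)
from rhythmscape.bands import Band, DensityCurve, EmergenceEvent

from conftest import make_dataset


def dist_from_values(values, day=50):
    return daily_distribution(values, day=day)


def gaussian_curve(weights_means_sds, day=50):
    """Analytic mixture density on the standard 1 ms grid."""
    grid = np.arange(0.0, 351.0)
    density = np.zeros_like(grid)
    for w, mu, sd in weights_means_sds:
        density += w * np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return DensityCurve(day=day, grid=grid, density=density, bandwidth=np.nan, n=1000)


class TestSmoothDistribution:
    def test_point_mass_peaks_at_value(self):
        dist = dist_from_values([100.0] * 50)
        curve = smooth_distribution(dist, bandwidth="scott")  # zero-spread fallback
        assert abs(curve.grid[np.argmax(curve.density)] - 100.0) <= 1.0

    def test_needs_two_values(self):
        with pytest.raises(SmoothingError):
            smooth_distribution(dist_from_values([100.0]))

    def test_single_gaussian_mode_recovered(self, rng):
        dist = dist_from_values(rng.normal(100, 10, 5000))
        curve = smooth_distribution(dist)
        bands = detect_bands(curve)
        assert len(bands) == 1
        assert bands[0].position == pytest.approx(100, abs=3)

    def test_two_component_mixture_gives_two_modes(self, rng):
        vals = np.concatenate([rng.normal(100, 10, 2500), rng.normal(250, 10, 2500)])
        bands = detect_bands(smooth_distribution(dist_from_values(vals)))
        assert len(bands) == 2
        assert bands[0].position == pytest.approx(100, abs=5)
        assert bands[1].position == pytest.approx(250, abs=5)

    def test_density_integrates_to_one(self, rng):
        dist = dist_from_values(rng.normal(175, 20, 3000))
        curve = smooth_distribution(dist)
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=0.02)

    def test_fixed_bandwidth_in_ms(self, rng):
        dist = dist_from_values(rng.normal(100, 10, 500))
        assert smooth_distribution(dist, bandwidth=6.0).bandwidth == 6.0
        with pytest.raises(ParameterError):
            smooth_distribution(dist, bandwidth=-1.0)


class TestDetectBands:
    def test_monotone_density_has_no_interior_band(self):
        grid = np.arange(0.0, 351.0)
        curve = DensityCurve(50, grid, np.exp(-grid / 80.0), np.nan, 100)
        assert detect_bands(curve) == []

    def test_prominence_threshold_is_monotone(self, rng):
        vals = np.concatenate(
            [rng.normal(m, 8, 400) for m in (60, 120, 180, 240, 300)]
        )
        curve = smooth_distribution(dist_from_values(vals), bandwidth=3.0)
        counts = [len(detect_bands(curve, p)) for p in (0.0, 0.05, 0.2, 0.6)]
        assert counts == sorted(counts, reverse=True)

    def test_plateau_reported_at_midpoint(self):
        grid = np.arange(0.0, 351.0)
        density = np.zeros_like(grid)
        density[100:111] = 1.0  # flat top from 100 to 110 ms
        curve = DensityCurve(50, grid, density, np.nan, 100)
        bands = detect_bands(curve)
        assert len(bands) == 1
        assert bands[0].position == pytest.approx(105.0, abs=0.5)

    def test_band_recovery_on_seeded_mixtures(self):
        """Planted m-component mixtures are recovered exactly (small study;
        the full replication study runs in the acceptance suite)."""
        ok = 0
        reps = 12
        for i in range(reps):
            rng = np.random.default_rng(300 + i)
            m = i % 6 + 1
            means = plant_separated_means(rng, m)
            sds = rng.uniform(5, 12, m)
            comp = rng.integers(0, m, 2000)
            vals = rng.normal(means[comp], sds[comp])
            bands = detect_bands(smooth_distribution(dist_from_values(vals)))
            if len(bands) == m and np.all(
                np.abs(np.sort([b.position for b in bands]) - np.sort(means)) <= 5
            ):
                ok += 1
        assert ok >= reps - 1


def plant_separated_means(rng, m, lo=40.0, hi=310.0, min_sep=40.0):
    """m means in [lo, hi] with pairwise separation >= min_sep."""
    slack = (hi - lo) - min_sep * (m - 1)
    u = np.sort(rng.uniform(0, slack, m))
    return lo + u + min_sep * np.arange(m)


class TestCountBandsByDecade:
    def test_single_day(self):
        table = count_bands_by_decade({"b1": {45: [None] * 3}})
        row = table.iloc[0]
        assert (row["decade"], row["mean_bands"]) == (40, 3.0)

    def test_mean_within_decade(self):
        table = count_bands_by_decade({"b1": {41: 2, 48: 4}})
        assert table.iloc[0]["mean_bands"] == 3.0

    def test_missing_decades_absent_not_zero(self):
        table = count_bands_by_decade({"b1": {45: 1, 95: 2}})
        assert sorted(table["decade"]) == [40, 90]


class TestTrackBands:
    def test_continuity_no_event(self):
        tracks, events = track_bands({60: [100.0], 64: [100.0]})
        assert len(tracks) == 1 and events == []
        assert tracks[0].positions == {60: 100.0, 64: 100.0}

    def test_new_band_opens_event(self):
        tracks, events = track_bands({60: [100.0], 64: [98.0, 130.0]})
        assert len(tracks) == 2
        assert tracks[0].positions[64] == 98.0
        assert len(events) == 1 and events[0].new_position == 130.0
        assert events[0].day == 64

    def test_first_day_bands_are_founders(self):
        _, events = track_bands({60: [100.0, 200.0]})
        assert events == []

    def test_converging_bands_tie_break(self):
        # both old tracks within threshold of the single new band: the
        # closer one wins; the other track ends
        tracks, events = track_bands({60: [100.0, 120.0], 64: [112.0]})
        assert len(tracks) == 2 and events == []
        assert tracks[1].positions == {60: 120.0, 64: 112.0}
        assert 64 not in tracks[0].positions

    def test_equal_distance_earlier_track_wins(self):
        tracks, _ = track_bands({60: [100.0, 120.0], 64: [110.0]})
        assert tracks[0].positions == {60: 100.0, 64: 110.0}

    def test_shuffled_band_order_is_canonicalized(self):
        a = track_bands({60: [100.0, 200.0], 64: [205.0, 95.0]})
        b = track_bands({60: [200.0, 100.0], 64: [95.0, 205.0]})
        assert [t.positions for t in a[0]] == [t.positions for t in b[0]]

    def test_band_objects_accepted(self):
        bands = {60: [Band(60, 100.0, 1.0, 1.0)], 64: [Band(64, 101.0, 1.0, 1.0)]}
        tracks, _ = track_bands(bands)
        assert tracks[0].positions[64] == 101.0


class TestAssignStem:
    def test_nearest_maximum(self):
        prior = gaussian_curve([(0.5, 110, 8), (0.5, 200, 8)])
        ev = assign_stem(EmergenceEvent(64, 130.0, 0), prior)
        assert ev.stem_position == pytest.approx(110, abs=1)
        assert ev.distance == pytest.approx(20, abs=1)

    def test_single_maximum(self):
        prior = gaussian_curve([(1.0, 120, 8)])
        ev = assign_stem(EmergenceEvent(64, 260.0, 0), prior)
        assert ev.stem_position == pytest.approx(120, abs=1)
        assert ev.distance == pytest.approx(140, abs=1)

    def test_equidistant_resolves_to_smaller_position(self):
        prior = gaussian_curve([(0.5, 100, 8), (0.5, 160, 8)])
        ev = assign_stem(EmergenceEvent(64, 130.0, 0), prior)
        assert ev.stem_position == pytest.approx(100, abs=0.5)

    def test_no_prior_band_flags_unassignable(self):
        grid = np.arange(0.0, 351.0)
        flat = DensityCurve(60, grid, np.full_like(grid, 1 / 351), np.nan, 100)
        ev = assign_stem(EmergenceEvent(64, 130.0, 0), flat)
        assert ev.unassignable


class TestClassifyEmergence:
    def test_zero_distance_is_branching(self):
        curve = gaussian_curve([(1.0, 150, 10)], day=64)
        ev = EmergenceEvent(64, 150.0, 0, stem_position=150.0, distance=0.0)
        assert classify_emergence(ev, {64: curve}) == "branching"

    def test_filled_valley_short_jump_is_branching(self):
        curve = gaussian_curve([(0.7, 150, 12), (0.3, 175, 10)], day=64)
        ev = EmergenceEvent(64, 175.0, 0, stem_position=150.0, distance=25.0)
        assert classify_emergence(ev, {64: curve}) == "branching"

    def test_empty_valley_distant_band_is_other(self):
        curve = gaussian_curve([(0.8, 150, 8), (0.2, 290, 8)], day=64)
        ev = EmergenceEvent(64, 290.0, 0, stem_position=150.0, distance=140.0)
        assert classify_emergence(ev, {64: curve}) == "other"

    def test_day_limit_excludes_late_events(self):
        curve = gaussian_curve([(1.0, 150, 10)], day=84)
        ev = EmergenceEvent(84, 150.0, 0, stem_position=150.0, distance=0.0)
        assert classify_emergence(ev, {84: curve}) is None

    def test_unassignable_excluded(self):
        ev = EmergenceEvent(64, 150.0, 0, unassignable=True)
        assert classify_emergence(ev, {}) is None

    def test_valley_ratio_is_monotone(self):
        curve = gaussian_curve([(0.7, 150, 9), (0.3, 180, 9)], day=64)
        ev = EmergenceEvent(64, 180.0, 0, stem_position=150.0, distance=30.0)
        labels = [
            classify_emergence(ev, {64: curve}, valley_ratio=r)
            for r in (0.0, 0.5, 0.9, 2.0)
        ]
        n_branching = [int(lbl == "branching") for lbl in labels]
        assert n_branching == sorted(n_branching, reverse=True)


class TestEmergenceStatistics:
    @staticmethod
    def _event(day, dist, cls):
        return EmergenceEvent(day, 100.0, 0, stem_position=100.0 - dist,
                              distance=dist, cls=cls)

    def test_class_means(self):
        events = [
            self._event(60, 20, "branching"), self._event(64, 30, "branching"),
            self._event(60, 70, "other"), self._event(68, 90, "other"),
        ]
        stats = emergence_statistics(events)
        assert stats["by_class"]["branching"]["distance_mean"] == 25.0
        assert stats["by_class"]["other"]["distance_mean"] == 80.0
        assert stats["distance_test"]["p"] < 0.05

    def test_single_event_single_class(self):
        stats = emergence_statistics([self._event(60, 20, "branching")])
        assert "other" not in stats["by_class"]
        assert "distance_test" not in stats

    def test_no_classified_events_errors(self):
        with pytest.raises(ParameterError):
            emergence_statistics([EmergenceEvent(60, 100.0, 0)])


class TestBandUsageRate:
    def test_window_counting(self):
        ds = make_dataset({50: [list(np.cumsum([0, 130, 133, 150, 131]))]})
        per_rec, _ = band_usage_rate(ds, window=(132, 4))
        assert per_rec.iloc[0]["fraction"] == 0.75

    def test_full_range_window_is_identity(self):
        ds = make_dataset({50: [[0, 100, 200], [0, 50]]})
        per_rec, per_day = band_usage_rate(ds, window=(175, 175))
        assert (per_rec["fraction"] == 1.0).all()
        assert per_day.iloc[0]["mean"] == 1.0

    def test_order_two_window(self):
        ds = make_dataset({50: [[0, 80, 160, 400]]})
        per_rec, _ = band_usage_rate(ds, window=(160, 4), order=2)
        assert per_rec.iloc[0]["fraction"] == 0.5  # order-2 IOIs [160, 320]

    def test_empty_recordings_excluded(self):
        ds = make_dataset({50: [[0, 100], [0]]})
        per_rec, per_day = band_usage_rate(ds, window=(100, 10))
        assert len(per_rec) == 1
        assert per_day.iloc[0]["n_recordings"] == 1

    def test_window_must_be_in_range(self):
        ds = make_dataset({50: [[0, 100]]})
        with pytest.raises(ParameterError):
            band_usage_rate(ds, window=(340, 20))
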