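"""Inter-onset intervals, daily distributions and developmental landscapes.

The inter-onset interval (IOI) between consecutive notes, IOI(i) =
t(s_{i+1}) - t(s_i), is the proxy for first-order rhythm: its distribution
reflects note-to-note transition timing.  Order-k intervals (onset differences
k notes apart) capture higher-order structure such as chunks.  Silent gaps are
the complementary quantity, gap(i) = IOI(i) - duration(i).

Two aggregations are built on top of the raw series:

* the per-day **IOI distribution** — a normalized 35-bin histogram on
  [0, 350] ms at 10 ms width, the unit compared by the Jensen-Shannon
  divergence and scanned for bands after kernel smoothing;
* the **landscape** — a normalized 2D histogram of feature values against
  developmental order (recording ID, or day post-hatch), default 300 x 300
  bins, rendering rhythm development as a single image.

Intervals never cross recording-file boundaries; within a file, intervals
longer than the 350 ms analysis range fall outside the histograms, so long
silences between song bouts are excluded without explicit bout segmentation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import EmptyDatasetError, ParameterError
from .notes_io import DevelopmentDataset, Recording

log = logging.getLogger(__name__)

#: quantitative analysis range (ms) and bin width for daily distributions
DEFAULT_RANGE: tuple[float, float] = (0.0, 350.0)
DEFAULT_BIN_WIDTH: float = 10.0
#: visualization default for landscapes
DEFAULT_LANDSCAPE_BINS: tuple[int, int] = (300, 300)

Feature = Literal["ioi", "duration", "gap"]


@dataclass
class IOISeries:
    """Ordered order-k inter-onset intervals of one recording."""

    recording_id: int
    day: int
    order: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GapSeries:
    """Silent gaps (offset-to-next-onset) of one recording.

    Negative gaps arise from overlapping detections and are dropped;
    ``n_overlaps_dropped`` records how many.
    """

    recording_id: int
    day: int
    values: np.ndarray
    n_overlaps_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class IOIDistribution:
    """Normalized per-day histogram of interval values.

    Bins are half-open [lo, hi) except the final bin, which is closed so a
    value exactly at the range maximum is retained.  ``values`` keeps the
    retained raw samples (the kernel density estimate is fit to these, not to
    the binned counts).  ``probs`` is ``None`` when no value fell in range
    (flagged empty rather than NaN-filled).
    """

    day: int
    counts: np.ndarray
    n: int
    values: np.ndarray
    bin_edges: np.ndarray
    smoothed: object | None = None  # DensityCurve, attached by bands.smooth_distribution

    @property
    def probs(self) -> np.ndarray | None:
        if self.n == 0:
            return None
        return self.counts / self.n

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass
class Landscape:
    """Normalized 2D histogram: development axis x milliseconds axis."""

    axis_x: np.ndarray  # bin edges over recording ID (or day)
    axis_y: np.ndarray  # bin edges over ms
    matrix: np.ndarray  # shape (nx, ny), sums to 1
    feature: str
    x_axis_kind: str
    n: int

    def marginal_feature(self) -> np.ndarray:
        """Pooled feature distribution (sum over the development axis)."""
        return self.matrix.sum(axis=0)

    def to_text(self, path: str | Path) -> Path:
        """Write the matrix as delimited text plus a JSON sidecar of axes."""
        path = Path(path)
        np.savetxt(path, self.matrix, delimiter="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "feature": self.feature,
                    "x_axis_kind": self.x_axis_kind,
                    "n": self.n,
                    "axis_x_edges": self.axis_x.tolist(),
                    "axis_y_edges": self.axis_y.tolist(),
                },
                indent=2,
            )
            + "\n"
        )
        return path

    def to_png(self, path: str | Path) -> Path:
        """Pseudo-color rendering, brighter = denser."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(
            self.matrix.T,
            origin="lower",
            aspect="auto",
            cmap="inferno",
            extent=(
                self.axis_x[0], self.axis_x[-1],
                self.axis_y[0], self.axis_y[-1],
            ),
        )
        ax.set_xlabel(self.x_axis_kind)
        ax.set_ylabel(f"{self.feature} (ms)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)


def compute_iois(rec: Recording, order: int = 1) -> IOISeries:
    """Order-k inter-onset intervals of one recording.

    Value j is ``onset(j + k) - onset(j)``; a recording with fewer than
    ``order + 1`` events yields an empty series.
    """
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    onsets = rec.onsets
    if len(onsets) <= order:
        values = np.empty(0)
    else:
        values = onsets[order:] - onsets[:-order]
    return IOISeries(rec.recording_id, rec.day, order, values)


def compute_gaps(rec: Recording) -> GapSeries:
    """Silent gaps between a note's offset and the next note's onset.

    gap(j) = onset(j+1) - (onset(j) + duration(j)); negative gaps (overlapping
    detections) are dropped and counted.
    """
    onsets = rec.onsets
    durations = rec.durations
    if len(onsets) < 2:
        return GapSeries(rec.recording_id, rec.day, np.empty(0), 0)
    gaps = onsets[1:] - (onsets[:-1] + durations[:-1])
    keep = gaps >= 0
    return GapSeries(
        rec.recording_id, rec.day, gaps[keep], int((~keep).sum())
    )


def _bin_edges(value_range: tuple[float, float], width: float) -> np.ndarray:
    lo, hi = value_range
    span = hi - lo
    n_bins = span / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ParameterError(
            f"bin width {width} does not divide range {value_range}"
        )
    return lo + width * np.arange(round(n_bins) + 1)


def daily_distribution(
    values: Sequence[float] | np.ndarray,
    day: int,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    width: float = DEFAULT_BIN_WIDTH,
) -> IOIDistribution:
    """Bin one day's interval values into a normalized histogram.

    Values outside ``value_range`` are excluded before binning (the range
    maximum itself is retained, in the final closed bin).  With the defaults
    this is the 35-bin, 10 ms-wide histogram on [0, 350] ms.
    """
    values = np.asarray(values, dtype=float)
    if values.size and not np.all(np.isfinite(values)):
        raise ParameterError("interval values must be finite")
    edges = _bin_edges(value_range, width)
    lo, hi = value_range
    retained = values[(values >= lo) & (values <= hi)]
    counts, _ = np.histogram(retained, bins=edges)
    return IOIDistribution(
        day=day,
        counts=counts.astype(int),
        n=int(retained.size),
        values=retained,
        bin_edges=edges,
    )


def feature_values(rec: Recording, feature: Feature, order: int = 1) -> np.ndarray:
    """Raw interval/duration values of one recording for a given feature."""
    if feature == "ioi":
        return compute_iois(rec, order).values
    if feature == "duration":
        return rec.durations
    if feature == "gap":
        return compute_gaps(rec).values
    raise ParameterError(f"unknown feature {feature!r}")


def daily_values(
    ds: DevelopmentDataset, feature: Feature = "ioi", order: int = 1
) -> dict[int, np.ndarray]:
    """Per-day pooled feature values (all recordings of a calendar day)."""
    out: dict[int, np.ndarray] = {}
    for day in ds.days:
        parts = [feature_values(rec, feature, order) for rec in ds.recordings_on(day)]
        out[day] = np.concatenate(parts) if parts else np.empty(0)
    return out


def daily_distributions(
    ds: DevelopmentDataset,
    feature: Feature = "ioi",
    order: int = 1,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    width: float = DEFAULT_BIN_WIDTH,
) -> dict[int, IOIDistribution]:
    """Normalized per-day distributions for the whole dataset."""
    return {
        day: daily_distribution(vals, day, value_range, width)
        for day, vals in daily_values(ds, feature, order).items()
    }


def build_landscape(
    ds: DevelopmentDataset,
    feature: Feature = "ioi",
    bins: tuple[int, int] = DEFAULT_LANDSCAPE_BINS,
    x_axis: Literal["recording", "day"] = "recording",
    value_range: tuple[float, float] = DEFAULT_RANGE,
    order: int = 1,
) -> Landscape:
    """Joint development x milliseconds histogram, normalized to sum 1.

    The development axis uses serial recording IDs by default (the
    visualization convention); ``x_axis='day'`` switches to days post-hatch,
    which quantitative analyses use.
    """
    if not ds.recordings:
        raise EmptyDatasetError("dataset has no recordings")
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for rec in ds.recordings:
        vals = feature_values(rec, feature, order)
        if vals.size == 0:
            continue
        x = rec.recording_id if x_axis == "recording" else rec.day
        xs.append(np.full(vals.size, x, dtype=float))
        ys.append(vals)
    if not xs:
        raise EmptyDatasetError(f"no {feature} values anywhere in the dataset")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    lo, hi = value_range
    in_range = (y >= lo) & (y <= hi)
    x, y = x[in_range], y[in_range]
    if x.size == 0:
        raise EmptyDatasetError(
            f"no {feature} values inside the {value_range} ms range"
        )
    x_edges = np.linspace(x.min(), x.max() if x.max() > x.min() else x.min() + 1, bins[0] + 1)
    y_edges = np.linspace(lo, hi, bins[1] + 1)
    matrix, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    total = matrix.sum()
    return Landscape(
        axis_x=x_edges,
        axis_y=y_edges,
        matrix=matrix / total,
        feature=feature,
        x_axis_kind=x_axis,
        n=int(total),
    )


def distributions_to_tsv(
    dists: Mapping[int, IOIDistribution], path: str | Path
) -> Path:
    """Export per-day distributions: day, bin_lo, bin_hi, count, prob."""
    import pandas as pd

    rows = []
    for day in sorted(dists):
        dist = dists[day]
        probs = dist.probs
        for i, count in enumerate(dist.counts):
            rows.append(
                {
                    "day": day,
                    "bin_lo": dist.bin_edges[i],
                    "bin_hi": dist.bin_edges[i + 1],
                    "count": int(count),
                    "prob": float(probs[i]) if probs is not None else float("nan"),
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)
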