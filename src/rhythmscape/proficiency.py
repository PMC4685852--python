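"""Rhythm proficiency: divergence trajectories toward the adult rhythm.

Proficiency — how complete rhythm development is — is measured by comparing
each recording day's interval distribution Q = {q_i} with the final recording
day's distribution P = {p_i} (the crystallized adult rhythm) using the
Jensen-Shannon divergence

    JS(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M),   M = (P + Q) / 2,

with KL(P || Q) = sum_i p_i log2(p_i / q_i).  In base 2 the JS is symmetric,
finite and bounded in [0, 1]; it approaches 0 as the developing rhythm
approaches the adult rhythm.  The per-bird JS-versus-age trajectory is
summarized by 10-day decade means from day 40, fit by an exponential decay
y = a e^{-bx} (x = day post-hatch), whose rate b is the speed of rhythm
development.  Crystallization — the age from which the distribution no longer
changes significantly — is located by paired comparisons of the cohort's
decade means against the terminal decade.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EmptyWindowError, FitError, ParameterError
from .notes_io import DevelopmentDataset
from .rhythm import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_RANGE,
    compute_iois,
    daily_distributions,
)

log = logging.getLogger(__name__)

DECADE_START = 40
DECADE_WIDTH = 10
CRYSTALLIZATION_ALPHA = 0.01


@dataclass(frozen=True)
class DivergenceResult:
    """A Jensen-Shannon divergence value in bits (base 2), in [0, 1]."""

    value: float
    p_day: int | None = None
    q_day: int | None = None
    base: int = 2

    def __float__(self) -> float:
        return self.value


@dataclass
class Trajectory:
    """Per-bird JS-versus-day trajectory against the final-day reference."""

    bird_id: str
    reference_day: int
    points: pd.DataFrame  # columns: day, js

    def decade_means(
        self,
        start: int = DECADE_START,
        width: int = DECADE_WIDTH,
        exclude_reference: bool = False,
    ) -> pd.DataFrame:
        """Mean JS per ``width``-day window from ``start``.

        ``exclude_reference`` drops the reference day itself (its JS is 0 by
        construction) before averaging — the convention used by the
        crystallization test and the decay fit.
        """
        pts = self.points
        if exclude_reference:
            pts = pts[pts["day"] != self.reference_day]
        if pts.empty:
            return pd.DataFrame(columns=["decade", "mean_js", "n_days"])
        decade = start + width * np.floor((pts["day"] - start) / width).astype(int)
        grouped = pts.groupby(decade)["js"]
        return pd.DataFrame(
            {
                "decade": grouped.mean().index,
                "mean_js": grouped.mean().values,
                "n_days": grouped.count().values,
            }
        ).reset_index(drop=True)


@dataclass
class ExpFit:
    """Least-squares exponential decay y = a exp(-b x)."""

    a: float
    b: float
    chi2: float  # sum of squared residuals at the fitted points
    n_points: int

    def predict(self, x) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float))


def _validate_probs(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ParameterError(
            f"distributions must be 1-D of equal length, got {p.shape} vs {q.shape}"
        )
    for name, arr in (("P", p), ("Q", q)):
        if np.any(arr < 0):
            raise ParameterError(f"{name} has negative entries")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ParameterError(f"{name} sums to {arr.sum()}, not 1")
    return p, q


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence KL(P || Q) in bits.

    Terms with p_i = 0 contribute 0; any p_i > 0 with q_i = 0 makes the
    divergence +inf.
    """
    p, q = _validate_probs(p, q)
    mask = p > 0
    if np.any(q[mask] == 0):
        return math.inf
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def js_divergence(
    p, q, p_day: int | None = None, q_day: int | None = None
) -> DivergenceResult:
    """Jensen-Shannon divergence in bits: symmetric, finite, in [0, 1]."""
    p, q = _validate_probs(p, q)
    m = 0.5 * (p + q)
    value = 0.5 * kl_divergence_unchecked(p, m) + 0.5 * kl_divergence_unchecked(q, m)
    return DivergenceResult(value=value, p_day=p_day, q_day=q_day)


def kl_divergence_unchecked(p: np.ndarray, q: np.ndarray) -> float:
    """KL sum without re-validation (inputs already checked/constructed)."""
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def js_trajectory(
    ds: DevelopmentDataset,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    width: float = DEFAULT_BIN_WIDTH,
    reference_day: int | None = None,
    order: int = 1,
) -> Trajectory:
    """JS of each recording day's interval distribution against the final day.

    One point per recording day (the reference day yields exactly 0); days
    with an empty distribution are skipped with a warning.
    """
    if len(ds.days) < 2:
        raise ParameterError("need at least 2 recording days for a trajectory")
    reference_day = ds.final_day if reference_day is None else reference_day
    dists = daily_distributions(ds, "ioi", order, value_range, width)
    if reference_day not in dists or dists[reference_day].empty:
        raise ParameterError(
            f"reference day {reference_day} has no interval distribution"
        )
    p = dists[reference_day].probs
    rows = []
    for day in sorted(dists):
        dist = dists[day]
        if dist.empty:
            log.warning("day %d: empty distribution, skipped", day)
            continue
        rows.append(
            {"day": day, "js": js_divergence(p, dist.probs, reference_day, day).value}
        )
    return Trajectory(
        bird_id=ds.bird_id,
        reference_day=reference_day,
        points=pd.DataFrame(rows, columns=["day", "js"]),
    )


def js_window(
    ds: DevelopmentDataset,
    day: int,
    window_a: tuple[float, float],
    window_b: tuple[float, float],
    value_range: tuple[float, float] = DEFAULT_RANGE,
    width: float = DEFAULT_BIN_WIDTH,
    order: int = 1,
) -> DivergenceResult:
    """JS between two within-day clock windows of one recording day.

    Windows are half-open hour intervals [h0, h1); each interval is assigned
    the wall-clock hour of its first note.  Raises
    :class:`EmptyWindowError` naming the window that contains no intervals,
    and :class:`ParameterError` when timestamps are absent.
    """
    from .rhythm import daily_distribution

    values: list[np.ndarray] = []
    hours: list[np.ndarray] = []
    for rec in ds.recordings_on(day):
        series = compute_iois(rec, order)
        if len(series) == 0:
            continue
        hr = rec.hours[: len(series)]
        if np.isnan(hr).any():
            raise ParameterError(
                f"recording {rec.recording_id} lacks timestamps; js_window needs them"
            )
        values.append(series.values)
        hours.append(hr)
    if not values:
        raise EmptyWindowError(f"day {day} has no intervals")
    vals = np.concatenate(values)
    hrs = np.concatenate(hours)

    def window_probs(name: str, win: tuple[float, float]) -> np.ndarray:
        sel = vals[(hrs >= win[0]) & (hrs < win[1])]
        dist = daily_distribution(sel, day, value_range, width)
        if dist.empty:
            raise EmptyWindowError(f"{name} {win} contains no intervals on day {day}")
        return dist.probs

    pa = window_probs("window_a", window_a)
    pb = window_probs("window_b", window_b)
    return DivergenceResult(value=js_divergence(pa, pb).value, p_day=day, q_day=day)


def fit_exponential(x, y, b_grid: np.ndarray | None = None) -> ExpFit:
    """Deterministic least-squares fit of y = a exp(-b x), b >= 0.

    A grid multi-start on b (amplitude solved in closed form at each b)
    followed by a bounded Levenberg-Marquardt-style polish; the best residual
    wins, so the fit is deterministic given the inputs and invariant to point
    order.  chi2 is the sum of squared residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise FitError(f"need >= 3 points, have {len(x)}")
    if np.any(y <= 0):
        raise FitError("all y must be > 0 for an exponential decay fit")
    if b_grid is None:
        b_grid = np.linspace(0.0, 1.0, 2001)
    best: tuple[float, float, float] | None = None
    for b in b_grid:
        w = np.exp(-b * x)
        denom = float(w @ w)
        if denom <= 0:
            continue
        a = float((y @ w) / denom)
        if a <= 0:
            continue
        r = float(np.sum((y - a * w) ** 2))
        if best is None or r < best[0]:
            best = (r, a, b)
    if best is None:
        raise FitError("no admissible (a, b) on the search grid")
    _, a0, b0 = best

    def residuals(theta):
        return theta[0] * np.exp(-theta[1] * x) - y

    sol = optimize.least_squares(
        residuals,
        x0=[a0, max(b0, 1e-12)],
        bounds=([1e-300, 0.0], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a, b = float(sol.x[0]), float(sol.x[1])
    chi2 = float(np.sum(residuals(sol.x) ** 2))
    # keep whichever of (grid best, polished) has the lower residual
    if best[0] < chi2:
        chi2, a, b = best
    return ExpFit(a=a, b=b, chi2=chi2, n_points=len(x))


def crystallization_test(
    cohort: pd.DataFrame,
    reference_decade: int | None = None,
    alpha: float = CRYSTALLIZATION_ALPHA,
) -> tuple[pd.DataFrame, int | None]:
    """Locate the crystallization decade of a cohort.

    ``cohort`` has one row per bird and one column per decade (start day of
    the 10-day window), holding per-bird decade-mean JS values (NaN where a
    bird has no data).  Each decade is compared with ``reference_decade``
    (default: the last decade) by a paired two-sided t test across birds at
    significance ``alpha``.  The crystallization decade is the earliest
    decade from which every later comparison (reference excluded) is defined
    and non-significant; None when that cannot be certified (e.g. a single
    bird, where no paired comparison is defined).

    Returns (per-decade table, crystallization decade).
    """
    if cohort.empty or len(cohort.columns) == 0:
        raise ParameterError("empty cohort table")
    decades = sorted(int(c) for c in cohort.columns)
    reference_decade = decades[-1] if reference_decade is None else reference_decade
    if reference_decade not in decades:
        raise ParameterError(f"reference decade {reference_decade} not in table")
    rows = []
    for decade in decades:
        if decade == reference_decade:
            rows.append(
                {
                    "decade": decade, "n_pairs": int(cohort[decade].notna().sum()),
                    "t": 0.0, "p": 1.0, "significant": False, "defined": True,
                }
            )
            continue
        paired = cohort[[decade, reference_decade]].dropna()
        n = len(paired)
        if n < 2:
            rows.append(
                {
                    "decade": decade, "n_pairs": n, "t": float("nan"),
                    "p": float("nan"), "significant": None, "defined": False,
                }
            )
            continue
        diffs = paired[decade] - paired[reference_decade]
        if float(np.std(diffs, ddof=1)) == 0.0:
            t_stat = math.inf if diffs.iloc[0] != 0 else 0.0
            p_val = 0.0 if diffs.iloc[0] != 0 else 1.0
        else:
            t_stat, p_val = stats.ttest_rel(paired[decade], paired[reference_decade])
        rows.append(
            {
                "decade": decade, "n_pairs": n, "t": float(t_stat),
                "p": float(p_val), "significant": bool(p_val < alpha),
                "defined": True,
            }
        )
    table = pd.DataFrame(rows)
    crystallization: int | None = None
    non_ref = table[table["decade"] != reference_decade]
    for decade in decades:
        tail = non_ref[non_ref["decade"] >= decade]
        if tail.empty:
            # nothing left to compare: only certifiable if some earlier
            # decade already qualified
            break
        if tail["defined"].all() and (~tail["significant"].astype(bool)).all():
            crystallization = decade
            break
    return table, crystallization


def cohort_decade_table(
    trajectories: Sequence[Trajectory],
    start: int = DECADE_START,
    width: int = DECADE_WIDTH,
    exclude_reference: bool = True,
) -> pd.DataFrame:
    """Bird x decade table of decade-mean JS values for a cohort."""
    series = {}
    for traj in trajectories:
        means = traj.decade_means(start, width, exclude_reference=exclude_reference)
        series[traj.bird_id] = pd.Series(
            means["mean_js"].values, index=means["decade"].values
        )
    table = pd.DataFrame(series).T
    table = table[sorted(table.columns)]
    table.index.name = "bird"
    return table
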