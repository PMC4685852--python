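# Methods

## The model of rhythm and its assumptions

rhythmscape treats rhythm as the distribution of durational patterns in a
note sequence. The atomic observable is the inter-onset interval (IOI)
between consecutive detected notes within one recording file,
`IOI(i) = t(s_{i+1}) − t(s_i)`; order-k intervals (onset differences k notes
apart) capture multi-note patterns such as chunks. The silent gap is
`gap(i) = IOI(i) − duration(i)`. Underlying assumptions:

- **Onset accuracy is the rhythm-bearing variable.** The analysis uses only
  note onsets and durations; acoustics (pitch, entropy, note identity) are
  out of scope.
- **Distributional sufficiency.** All quantities are computed from per-day
  *distributions* of intervals, not from sequential order within a bout. The
  method emphasizes stable dominant transition timings (bands) rather than
  individual transitions.
- **File-locality.** Intervals never span recording-file boundaries, and the
  0–350 ms analysis range excludes between-bout silences implicitly, so no
  bout segmentation is needed.
- **The final recording day is the crystallized reference.** Proficiency is
  dissimilarity to that day's distribution; the choice can be overridden.

## Pipeline and parameter defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| noise filter bounds | 15, 350 (inclusive) | ms | detected sounds outside this duration range are overwhelmingly detection noise; removing them improves IOI accuracy |
| histogram range / bin width | [0, 350] / 10 | ms | 35 bins; bins half-open [lo, hi), last bin closed so 350 is retained |
| landscape bins | 300 × 300 | – | visualization resolution only; quantitative analyses use the 35-bin day distributions |
| KDE kernel / width | Gaussian, fixed 4 | ms | see "Bandwidth" below; `"scott"` or any fixed ms width selectable |
| KDE grid | 1 | ms | fine enough that band positions are read off the grid |
| band prominence floor | 0.05 × day max density | – | rejects sampling wiggles at realistic day sizes (≥ ~8000 intervals) while keeping minority bands with ~2× lower peak |
| band-linking threshold | 30 | ms | bands drift ≤ ~20 ms between 4-day-spaced recordings; 30 ms separates drift from genuine new bands |
| valley ratio (branching call) | 0.5 | – | "continuous branching" = the density between stem and new band stays above half the lower of the two peaks |
| distance cap (branching call) | 60 | ms | sits between the empirical branching (~25 ms) and de-novo (~78 ms) distance regimes |
| emergence analysis window | day < 80 | days | band emergence concentrates before day 80; later appearances are re-detections and edge effects |
| decade binning | 10-day windows from day 40 | days | recording design starts near day 40; decade means feed the fit and the crystallization test |
| crystallization α | 0.01 | – | paired two-sided t-test per decade against the terminal decade, no multiplicity correction (planned comparisons) |

The exponential decay `y = a·e^(−b·x)` is fit to decade-mean JS values by
least squares with `x` = decade midpoint in days post-hatch: a grid
multi-start over `b ∈ [0, 1]` (2001 points, amplitude solved in closed form
at each `b`) followed by a bounded least-squares polish, best residual wins —
deterministic and invariant to point order. `chi2` is the plain sum of
squared residuals.

### Bandwidth

The daily density is a Gaussian-kernel estimate fit to the raw retained IOI
values (not to the 10 ms histogram, which would double-bin), evaluated on a
1 ms grid. The default kernel width is a **fixed 4 ms** rather than a
spread-based rule: Scott's rule scales with the standard deviation of the
whole sample, and in a banded distribution most of that spread lies *between*
bands — at day sizes of 2000–8000 it yields 12–20 ms kernels that merge bands
separated by 40 ms. 4 ms matches the within-band jitter of crystallized song
(≈ 4–12 ms) and resolves bands ≥ ~25 ms apart once jitter has annealed, while
averaging enough samples per grid point to keep noise peaks below the 5%
prominence floor at realistic day sizes. Scott's rule remains available for
strictly unimodal material, and any fixed ms width can be passed for
sensitivity analysis.

### Divergences

KL and JS are computed in base 2, so JS ∈ [0, 1]; terms with `p_i = 0`
contribute 0, and within JS the midpoint distribution `M = ½(P + Q)` makes
every term finite. `kl_divergence` returns `+inf` on support violations.
Empty day distributions are flagged empty (probabilities `None`), never
NaN-filled, and skipped with a warning by the trajectory.

### Crystallization convention

The reference day's own JS is identically 0 by construction, which would
bias the terminal decade's mean low and could make the paired test flag a
spurious difference against other post-crystallization decades. The decade
means fed to the crystallization test therefore exclude the reference day
itself (`decade_means(exclude_reference=True)`); trajectory plots keep it.

## The synthetic generator

`synthetic.simulate_development` draws each day's IOIs i.i.d. from a mixture
of Gaussian bands with day-scheduled means, jitter SDs and weights
(piecewise-linear schedules). Onsets accumulate as running sums split into 4
recording files per day; durations are Gaussian (40 ± 10 ms) clipped to
[15 ms, following IOI − 2 ms] so every note survives the noise filter and
gaps stay positive; wall-clock timestamps spread uniformly over the day
(an optional within-day weight step supports the hourly-comparison analysis).
IOI draws are clipped to [20, 350] ms. Fixed seed ⇒ byte-identical output.

`preset_paperlike` is the standard scenario: 28 recording days (40–148,
every 4 days), 8000 notes/day — the "thousands per day" regime of real 24 h
recordings, kept desk-scale (a real bird's corpus runs ~18k notes/day). A
broadband founder starts offset at ~250 ms with 45 ms jitter and drifts to
175 ms while annealing to 8 ms; three branching children split off at days
56/64/68 at planted stem distances ~N(25, 8) ms (children planted relative
to the stem's prior-recording-day position, so the planted distance is
exactly the drawn value) and drift outward; one de-novo band appears at day
60 at ~N(78, 10) ms from the stem. Five terminal bands
(≈ 95/128/175/213/255 ms) result. All schedules freeze at day 90: the JS
trajectory decays roughly exponentially (decade-mean fit b ≈ 0.05/day) to a
sampling floor and flattens — planted crystallization at day 90.

**What the generator does and does not emulate.** It reproduces the
distributional phenomena the pipeline measures: band formation by branching
and de-novo emergence, annealing jitter, an exponential-looking proficiency
trajectory, intermittent recording days, and realistic day sizes. It does
not model song syntax, bout structure, acoustic features, inter-day variance
beyond sampling noise, or drift after crystallization. Passing recovery
tests therefore demonstrates that the *pipeline* recovers planted
distributional structure at realistic sizes — not that real song satisfies
the mixture model.

**Recovery caveats established with the simulator.**

- A branching child planted < ~25 ms from its stem is physically
  unresolvable (no second local maximum exists) until it drifts out; first
  detection lags the planted birth by 1–3 recordings. Ground-truth matching
  therefore tolerates ±12 days and ±25 ms.
- For the same reason the *recovered* first-appearance distance of branching
  events concentrates near the resolvability threshold (~30 ms) with little
  variance, regardless of the planted draw: the detection process itself
  censors smaller separations. Real data, with heterogeneous band widths,
  shows more spread.
- The mode of a broad band (SD ~50 ms) jitters ±10 ms day-to-day at
  realistic day sizes; position recovery to ±5 ms holds per-day only for
  annealed bands (SD ≤ 12 ms), and for broad bands on the across-day mean.

## Numerical and degenerate-input choices

- Histogram bins half-open with a closed final bin; values outside the range
  are excluded before normalization; an all-outside day is flagged empty.
- KDE requires ≥ 2 values; a zero-variance sample under `"scott"` falls back
  to a 2 ms kernel (the rule's width would be 0).
- Grid endpoints are never bands; plateau maxima are reported at the plateau
  midpoint.
- Band linking is greedy nearest-neighbour, ties broken by smaller distance
  then earlier track id; within-day band order is canonicalized by sorting,
  so input order cannot change tracks.
- Stem assignment ties (equidistant prior maxima) resolve to the smaller
  position. A zero-distance emergence is trivially branching.
- Events with no prior-day band are flagged unassignable and excluded from
  distance statistics; events at/after the day limit are excluded from
  classification.
- Rows of a note table whose mandatory numerics do not parse are dropped and
  counted, not fatal (field data are messy); a file with no valid rows is an
  error. Floats are written via `repr` and parsed with Python's `float` so
  a write/read cycle is exact.
- The fit rejects non-positive `y` (an exponential decay cannot pass through
  0) and degenerate all-zero input; a constant series fits `b = 0`.
- Paired comparisons with fewer than 2 pairs are reported undefined, and the
  crystallization decade is only certified when every later comparison is
  defined and non-significant (a single bird yields "undefined", not a
  decade).

## Known limitations

- The branching/other call operationalizes a judgment that is partly visual
  in practice; the valley-ratio and distance-cap defaults were chosen from
  the two distance regimes the method targets and are configurable, but no
  claim is made that they match any particular human rater.
- With ~4-day recording gaps, a band that genuinely arose by branching
  between recordings can first appear far from its stem and be classified
  "other"; the method cannot distinguish these (an inherent censoring of
  intermittent designs).
- JS between finite samples has a positive noise floor (≈ (k−1)/(4n ln 2)
  bits); trajectories never reach exactly 0 off the reference day.
- The landscape's development axis uses recording IDs for visualization;
  quantitative statements should use days post-hatch (`x_axis="day"`).
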