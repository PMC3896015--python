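# Methods

## Grid and time conventions

All surfaces live on a regular latitude–longitude grid crossed with the four
annual quarters (Q1 = Jan–Mar … Q4 = Oct–Dec). The default cell size is 5°,
the coarsest resolution at which basin-wide public longline statistics are
reported; any size dividing both 360 and 180 is accepted. Longitude is kept
in [0, 360) internally so the Pacific is contiguous across the antimeridian;
readers accept both sign conventions. Cells are half-open boxes
`[lo, lo+5) × [lo, lo+5)` anchored at multiples of the cell size (the edge
registration is a convention choice; nothing downstream depends on it), with
latitude 90 folded into the top row so every valid point has exactly one
cell. Years are pooled: all data collapse onto the four quarters, which
assumes spatio-temporal use patterns are stable across years.

A `QuarterlyField` stores only non-masked entries: an absent (cell, quarter)
is *no data* and is excluded from every sum and normalization, while a
stored `0.0` is a real zero (e.g. reported zero effort). This single
distinction carries the missing-data semantics through the whole pipeline:
an interaction value exists only where both inputs have data.

## Track pre-processing

Inputs are daily regularized positions (one per calendar day), the standard
output of state-space filtering of raw satellite fixes; the filtering itself
is outside this package's scope. Daily positions lying strictly inside an
observation gap longer than 20 days (i.e. more than 20 days with no real
fix between two observed days) are removed, because interpolated positions
across such gaps are unreliable; the bracketing observed days are kept. A
track whose positions all fall inside long gaps is dropped with a log entry
and a QC-table row.

Relative track day is then assigned as calendar days since deployment
(day 1 = first position), and holes left by gap removal stay holes — the
numbering is never compacted. This keeps the per-day sample size `n_jt`
indexed by true time since deployment, which is what the weighting scheme
needs. When the input carries no explicit observation dates (pre-thinned
daily series), the dates present are taken as the observations, so holes
are already gaps and nothing further is removed. The synthetic generator
writes an optional `observed` 0/1 column precisely so that filter-style
tracks (positions on every day, gaps flagged) exercise the removal rule.

## Inverse-sample-size weighting

The weight of a day-*t* position of population *j* is `ω = 1/n_jt`, so each
relative day contributes total weight exactly 1 per population while any
animal is still transmitting. Two numerical conventions are deliberate:

* **Threshold day.** `T_j` is the smallest day *d* at which the cumulative
  fraction of the population's position-days reaches q = 0.85 (a ≥ rule on
  the position-day distribution, not on per-track durations, and with no
  interpolation). Past `T_j`, weights are capped at `1/n_{j,T_j}`. The 85%
  default follows simulation work showing it minimizes bias across tracking
  scenarios; it is configurable.
* **Quarter inflation.** Per quarter, raw (unweighted) position counts
  define x (larger) and y (smaller); the smaller population's positions are
  multiplied by x/y, the larger's by 1; a quarter with a single population
  gets 1. Inflation multiplies ω at accumulation time; thresholding and
  inflation act on different factors of the same product, so their order
  does not matter.

Weighted, inflated positions are summed into (cell, quarter) bins per
population. The per-population surfaces are kept separate throughout;
merging is an explicit operation, since downstream comparisons treat the
populations as separate management units.

Invariants tested: for every t ≤ T_j the binned weights at day t sum to 1
exactly (checked in exact rational arithmetic against the enumeration
oracle, and to 1e−12 in floating point); for t > T_j they sum to
`n_jt / n_{j,T_j}`; identical gap-free tracks give uniform weights; the
field total equals the sum of per-position contributions.

## Gear adjustment

The catchability index divides turtles per hook in billfish-configured sets
by turtles per hook in tuna-configured sets; with the default per-set rates
(0.0246, 0.0048) and set sizes (850, 1124 hooks) it evaluates to 6.78,
assumed constant over the whole domain. Raw hooks are converted to
tuna-hook equivalents by the convex mix `hooks · [p·c + (1−p)]`, where *p*
is the billfish share of catch weight in that cell-quarter, pooled across
years. The mix is the default because *p* is introduced exactly as an
estimate of the share of effort targeting billfish; a `literal` mode
(`hooks · c` everywhere) is provided as a configuration switch for
comparison. Cells with hooks but no catch data receive a configurable
default *p* (the basin-wide pooled mean unless overridden) rather than
being dropped, so coverage holes in the catch source do not silently erase
risk surface. Species names map onto the tuna/billfish groups via an
extensible lookup (swordfish/marlin/sailfish → billfish, etc.).

## Interaction index

Each surface is normalized by its grand total over all non-masked
cell-quarters (compensated summation via `math.fsum`), giving relative
probabilities that sum to 1 across space *and* season. The interaction
index is the product of the two probabilities renormalized over the joint
support; an empty joint support or an all-zero product raises a diagnostic
error rather than returning a degenerate surface. Hotspots are ranked
descending with ties broken by (quarter, lat_lo, lon_lo) ascending so
reports are deterministic. Equality assertions in tests use 1e−9 for
normalization totals and 1e−12 against the brute-force oracle.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes, not
ocean realism:

* **Durations** are lognormal (σ = 0.9, mean parameterized at 209 days)
  truncated by rejection to [4, 948] days — the observed range in the
  motivating study. Truncation pulls the realized mean to ≈180–200 days,
  within the ±25% band the duration test allows. Deployments are uniform
  over 1992–2008, constrained so each track fits the window.
* **Movement** is a two-state switching correlated random walk — transiting
  (fast, persistent heading, drawn toward a per-animal migration target)
  vs area-restricted search (slow, high turning) — with steps in degrees
  and a cos(latitude) longitude correction; at 5° resolution projection
  error is immaterial. Positions reflect off a per-population envelope box.
  The east-Pacific and west-Pacific envelopes are disjoint with a >2-cell
  longitude buffer, which is what guarantees the two populations never
  share a 5° cell — mirroring the observed non-overlap, by construction
  rather than by accident.
* **Gaps**: up to two per track, each present with probability 0.35,
  lengths 1 + Geometric(0.08) days so roughly a sixth of gaps exceed the
  20-day removal threshold and the rule gets real work.
* **Effort**: lognormal hooks per cell-quarter around a baseline with
  regional multiplier boxes; billfish fraction piecewise-constant in space;
  an optional coverage mask; catch tonnage proportional to hooks and split
  between the groups *exactly* at the configured fraction (a deliberate
  zero-noise choice that keeps the composition oracle exact).
* **Scenarios**: `null_overlap` (one population, uniform independent
  effort), `planted_hotspot` (half the animals attracted into one known
  cell during one quarter plus a 10× hooks multiplier there — the recorded
  ground truth), and `paper_like` (both populations at the full study
  sample size of 135 animals with an Indo-Pacific / central-Pacific /
  south-Pacific-gyre effort structure and a billfish-heavier north
  Pacific). All generators are deterministic given the seed; the effort
  stream is decoupled from the track stream by a fixed seed offset.

What passing tests therefore show: the estimator chain is arithmetically
correct, conserves weight, normalizes, recovers a strong planted joint
signal, and keeps disjoint populations disjoint. What they do not show:
performance on real Argos error structure, real fleet behaviour, real
catch-composition noise, or interannual variability — none of which the
generator attempts to emulate.

## Problem sizes and defaults

Default analysis parameters are the published values: 5° cells, quarterly
pooling, 20-day gap threshold, q = 0.85, the gear parameters above, `mix`
adjustment. Test and acceptance runs use the scenario sizes stated there:
20 animals for the planted/null scenarios (20-seed recovery sweeps), 135
for the two-population scenario; these sizes give stable results while
keeping a full suite run in a few seconds.

## Known limitations

The index is relative: it ranks cell-quarters, and says nothing about
absolute bycatch counts or rates. Catchability is assumed spatially
constant. Year pooling assumes stationarity of both turtle use and effort.
The percentile and inflation conventions above are explicit choices where
reasonable alternatives exist (per-track-duration percentiles, ω-weighted
inflation counts); both are isolated in single functions if a user needs a
different convention.
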