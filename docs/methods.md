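# Methods

## Model

The field is an M × N lattice of crop zones, one sensor station per
zone.  State per zone: crop health in [0, 100] (%), two fumigation
flags (this hour / previous hour) and a cumulative pesticide ledger.
Bugs are individual agents with a position (zone granularity), an
alive flag and a cumulative exposure counter.  Time advances in
one-hour steps through a fixed phase order:

1. **flag shift** — `fumigated_now` of the previous hour becomes
   `fumigated_prev`; the per-hour message and activity ledgers reset;
2. **appearance** — one uniform draw `ra`; if `ra < p_appear`, a count
   `db ~ Uniform{0, …, Mb}` of new bugs is placed, each at an
   independent uniform-random zone;
3. **movement** — each alive bug, in creation order, shifts each
   coordinate by an independent uniform draw from {−1, 0, +1}, clamped
   to that coordinate's index range (bugs never leave the grid and move
   at most one zone per hour, Chebyshev metric);
4. **periodic hooks** — every sensor's `live` hook runs in row-major
   raster order; messages are delivered synchronously (the receiver's
   `manage` hook runs inline during the sender's turn), so a warning
   takes effect the same hour it is sent;
5. **exposure** — bugs standing in a zone fumigated *this* hour accrue
   one exposure-hour; a bug dies when its cumulative (not necessarily
   consecutive) count reaches `h_die`;
6. **eating** — surviving bugs each remove `eat_rate` percentage points
   from their zone's health (floored at 0) unless the zone was
   fumigated the *previous* hour.  Same-hour fumigation deliberately
   does not protect the crop: it drives exposure instead, and the
   protective residue is only assumed effective from the next hour on;
7. **regrowth** — every zone gains `grow_rate` points, capped at 100;
8. **observation** — the four metrics are appended to the trace.

The phase order is a modelling commitment, not a mathematical
necessity; it is fixed and documented because it affects traces
(e.g. a bug appearing at hour *t* is detectable at hour *t*, and dies
at the earliest at hour *t* + `h_die` − 1).

A single `numpy.random.Generator`, seeded from the configuration,
drives phases 2–3; strategies draw no randomness.  The draw order is
fixed by the phase order, so identical (config, seed) pairs produce
bitwise-identical traces.

## Strategies

Strategies see the world only through six sensor capabilities —
`sense_bugs` (perfect detection of alive bugs in the own zone),
`fumigate` (idempotent within the hour: one pesticide quantum per zone
per fumigated hour regardless of call count), `send` (stamps sender
position and hour, accrues `E_msg` energy, delivers synchronously),
`broadcast`, `send_neighbors` (boundary-clipped 8-neighbourhood) and
`get_iteration`.  Reactive hooks never send messages, so there are no
cascades and the per-hour message count is bounded by
(detecting sensors) × (M·N − 1).

The low-cost neighbour strategy keeps, per sensor, the last-detection
hour `b` and a 3 × 3 last-warnings matrix `W` indexed by local offset
(`local = global − reference + (1, 1)`; the centre cell is the sensor
itself).  Its periodic rule at hour *t*: on a fresh detection
(`t − b > d`) it warns every in-bounds neighbour whose `W` entry
satisfies `t − W > d` and sets `b := t`; it fumigates whenever
`t − b ≤ d`.  Evaluating the window test after the assignment makes a
detecting sensor fumigate the same hour (its neighbour-strategy
analogue does) and then keep fumigating through `t + d`.  Its reactive
rule: fumigate this hour and record the sender's warning time in `W`.
`b` and all `W` entries initialise to −∞, so nothing is suppressed
before the first event.  Two readings of the printed rules were
resolved as design choices: the broadcast/neighbour exclusion condition
is interpreted as "exclude only the sender's own cell" (warning sets
would otherwise skip same-row/column sensors, contradicting the prose
definition of both primitives), and a warned low-cost sensor fumigates
only the current hour, not a full window.

## Metrics

* **Average power per active station** — a station is active in an hour
  if it sent ≥ 1 message or fumigated.  Instantaneous power of an hour
  with ≥ 1 active station is (messages × `E_msg`) / (active stations);
  the reported value is the running mean over such hours (0 before any
  activity).  Hours with no active stations are excluded rather than
  counted as zero, which keeps the curve a stable per-activity
  average.  Fumigation makes a station active (it is awake and doing
  work) but contributes no energy to the numerator, which meters
  communication only.
* **Crop health** — mean zone health, %.
* **Alive bugs** — 100 × alive / total-ever, reported as 100 before any
  bug has existed.
* **Pesticide per station** — cumulative dispensed total / (M·N);
  non-decreasing by construction.

## Parameters

| parameter | default | unit | note |
|---|---|---|---|
| columns × rows | 10 × 16 | zones | standard scenario grid |
| initial_affected_areas | 2 | zones | distinct, uniform-random |
| p_appear | 0.10 | 1/h | appearance probability |
| max_new_bugs (Mb) | 3 | bugs | count uniform on {0..Mb} |
| hours | 48 | h | standard run length |
| fumigation_window (d) | 3 | h | low-cost window & suppression horizon |
| bugs_per_initial_area | 1 | bugs | |
| exposure_hours_to_die (h_die) | 3 | h | cumulative |
| eat_rate | 2.0 | %/h per bug | |
| grow_rate | 0.1 | %/h | must stay < eat_rate |
| energy_per_message (E_msg) | 1.0 | energy units | calibration |
| pesticide_per_fumigation (q) | 1.0 | volume units | calibration |

Grid size, initial infestations, appearance probability and duration
are the standard scenario; the remaining defaults are modelling
choices: a "few hours" of lethal exposure and a matching fumigation
window are both set to 3 h, at most a handful of bugs per appearance
event, and an eating rate 20× the regrowth rate so that infestation
damage is decisively faster than recovery.  `E_msg` and `q` are unit
calibrations: absolute power/pesticide outputs are expressed in these
units, and only calibration-free quantities (orderings, ratios,
p-values, Cohen's d) are meaningful across calibrations.

## Statistics

Batches of n replicate runs per strategy (replicate *i* seeded
`base_seed + i`; strategy batches offset by a 10⁶ stride) feed:
Levene's test (mean-centred, via scipy; median-centring available),
Welch's heteroscedastic one-way test and the Brown–Forsythe test of
equality of means (both implemented from their textbook formulas —
the Brown–Forsythe *means* test, variance-weighted F with Satterthwaite
denominator df, is not the median-centred Levene variant of the same
name and is not available in the installed statistics packages), and
pooled-SD Cohen's d.  For two equal-sized groups both robust tests
reduce exactly to the squared Welch t with the Welch–Satterthwaite df,
which is why two-group report rows show identical Welch and
Brown–Forsythe lines.  Degenerate inputs (any group with zero
within-group variance, all-constant Levene data, zero pooled SD) raise
errors at the function level; the report builder records such cells as
NaN instead of aborting, since tiny exploratory batches legitimately
produce constant columns.  No multiple-testing correction is applied.

## Scripted scenarios

`ScenarioScript` injects bugs at scripted (hour, zone, count)
directives and can disable stochastic appearance and movement.  Runs
under a fully scripted scenario are deterministic, which the test suite
uses to compare the engine trace-for-trace against an independent
brute-force reference implementation on 2 × 2 and 3 × 3 grids for all
three strategies.  Scripts model none of the stochastic structure of
real infestations (spatial clustering, weather dependence); they exist
to make protocol semantics exactly checkable.

## What the synthetic scenarios do and do not show

The generator emulates the study conditions: sparse stochastic
appearance on a 160-zone field over 48 h, perfect detection, bugs at
zone granularity, one bug species, flat propagation costs.  Passing
tests therefore demonstrate protocol-level properties (coverage,
suppression, energy ordering, extermination) under these idealisations
— not field performance with imperfect detection, grouped bug flight,
weather-driven appearance or distance-dependent radio cost, all of
which are out of scope.

## Problem sizes

The end-to-end comparisons use 100 replicates per strategy of the
standard 10 × 16 × 48 h scenario (the study's replicate count) and 50
seeded runs per strategy for the appearance-free extermination check;
a full acceptance evaluation completes in a few seconds on one CPU.

## Known limitations

* Sub-zone bug positions are not modelled; all dynamics and metrics
  operate on zones.
* Detection is perfect and instantaneous; no false negatives.
* Message delivery is lossless, instantaneous and free of contention;
  energy per message is constant regardless of distance.
* The power metric meters communication energy only; if fumigation
  also drew metered power, absolute power levels would shift
  (orderings would not, since fumigation already counts toward the
  active-station denominator).
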