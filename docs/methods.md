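# Methods

## Input model

The algorithm operates on the mean instantaneous heart rate per 10-s
section — the standard CSV product of beat-interval (HRV) analysis
software fed by a bedside ECG monitor. `HRSeries` holds that series on
a uniform, gapless grid: section `i` covers the half-open span
`[start_time + 10·i, start_time + 10·(i+1))` seconds. The half-open
convention anchored at `start_time` is a package convention: exporters
do not document how their 10-s averages align to the video clock, and
some fixed choice is needed for rasterizing annotations onto the same
grid. Non-uniform or gapped grids are rejected at read time rather than
resampled — the extraction rules are defined on a fixed 10-s grid, and
any resampling policy would be an invention layered on top of them.
RR-interval detection and beat-to-beat variability metrics are out of
scope; the package starts from the 10-s product.

## Features and extraction rules

Per section, with a trailing window of `w = 6` sections (60 s):

* `MovAvHR[i] = mean(HR[i-6 .. i-1])`,
* `dHR[i] = HR[i] − MovAvHR[i]`,
* `%dHR[i] = 100 · HR[i] / MovAvHR[i]`.

The window excludes the current section. The past average is the
baseline the current value is contrasted against; including the current
section would fold 1/6 of the excursion into its own baseline and
dampen `dHR` accordingly. Because the alternative reading is also
coherent, it is available as `window_includes_current` (then features
are defined from section `w−1` instead of `w`). Sections without a full
trailing window have undefined features: they can neither seed a
candidate run nor be absorbed by expansion.

Candidate runs are maximal runs of consecutive sections with `dHR > 0`,
kept when they span at least `min_run = 3` sections and contain at
least one section with `%dHR` strictly above the threshold
(`threshold_pct`, default 105; 103 is the documented sensitive
setting). All comparisons are strict: `dHR == 0` is neither positive
nor negative. Exact zeros are measure-zero on real data but occur in
integer-valued test data, so the tie behaviour is pinned deliberately.
The supra-threshold section may sit anywhere in the run, not only among
its first three sections — the rule conditions the run as a whole.

Each run is expanded outward, each flank independently, one section at
a time, counting sections with `dHR < 0`. A flank stops at the record
boundary, at the first undefined-feature section, or when the negative
count would reach two; the section carrying the second negative is
excluded, so each flank contains at most one negative section. Reading
"until the second deceleration" as inclusive is equally defensible, so
`include_second_negative=True` flips the boundary; the default excludes
it because the emitted sections are clips a reviewer must watch, and a
sustained deceleration adds nothing to review. Expanded spans that
overlap or share a boundary merge into one AES (overlapping review
clips are meaningless); merging is idempotent. No minimum AES duration
is imposed: an unexpanded 3-section run yields a 30-s AES.

Useful invariants, all under test: the extraction is invariant to
scaling all HR values by a positive constant (both conditions are
ratios or sign tests); lowering the threshold can only grow the
extraction (every AES at 105 is contained in an AES at 103); and the
whole pipeline is deterministic.

## Annotations and concordance

GM annotations are `(start, end)` intervals on the recording clock.
Intervals shorter than `min_gm_seconds = 20` are rejected with a
reason — movements below 20 s are isolated or reflex movements, not
GMs — and overlapping survivors raise, since non-overlap is part of
what a GM annotation means. Artifact intervals (care interventions,
electrode detachment, ...) carry a free-text label.

Rasterization flags a section when an interval overlaps any
positive-length part of it. The annotation convention marks a section
containing only a GM's beginning or end as a GM section; generalizing
to "any overlap" is the only reading consistent with interior sections
trivially being GM sections. With half-open sections, an interval
ending exactly on a boundary does not flag the following section.

The four metrics, per recording:

1. AES accompanied by GMs: an AES counts when ≥ 1 of its sections is a
   GM section.
2. Full-course GMs among GMs with AES: a GM is full-course when every
   one of its rasterized sections lies inside a *single* AES — a GM
   straddling two disjoint AESs is accompanied but not full-course,
   because neither clip shows the whole movement.
3. GMs accompanied by an AES: ≥ 1 rasterized GM section inside some AES.
4. AES length / recording length: artifact sections are removed from
   both numerator and denominator.

Artifact policy: by default (`drop-events`) any AES or GM touching an
artifact section is also excluded from the event counts of metrics
1–3 — the most conservative reading of "excluded from the
examination". `mask-sections` instead keeps the events and ignores
their artifact sections. Percentages with a zero denominator are
explicit missing values (`None`/JSON `null`), never 0 or 100, so
pooling stays correct.

Pooling across recordings sums counts and seconds and recomputes
percentages from the pooled totals — not the mean of per-recording
percentages — and reports the mean number of full-course GMs per
recording alongside. Per-recording reports remain available, so a
per-infant averaging can be produced by the caller if wanted.

## Synthetic recordings

`simulate_recording` emulates what the algorithm assumes about a
preterm infant at rest. Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `duration_s` | 3600 | one-hour recording; clinical sessions run ~35–90 min |
| `baseline_bpm` | 155 | typical preterm resting HR |
| `noise_sd_bpm` / `ar1_coeff` | 2.0 / 0.6 | stationary AR(1) at section resolution; ~1.3 % section-to-section variability with short-range correlation |
| `gm_rate_per_hour` | 12 | of order ten GM episodes per hour-long session |
| `gm_duration_range_s` | (20, 120) | GMs last 20 s by definition, up to a couple of minutes |
| `accel_amplitude_pct` | 8 | peak HR elevation during a GM, a few percent of the local baseline |
| `accel_rise_s` / `accel_decay_s` | 10 / 10 | gradual beginning and end |
| `blip_*` | 6/h, 2 %, 5 s | isolated limb movements: short, tiny HR change |
| `artifact_*` | 1/h, 60 s | care interventions etc. |

GM onsets are a Poisson process thinned to forbid overlap; durations
are uniform in range; every generated GM satisfies the ≥ 20 s and
non-overlap invariants by construction. The acceleration multiplies the
baseline by a trapezoidal rise–plateau–decay profile peaking at
`1 + amplitude/100` (ramps shrink proportionally for short episodes),
sampled on a 0.5-s grid and averaged per section — the algorithm only
ever sees section means, so beat-level simulation would add nothing
testable. The simulation is AR(1)-plus-events, not a physiologically
validated HRV spectrum: no sleep-state cycling, no respiratory
modulation, no posture model. Consequently the synthetic false-positive
floor is lower than clinical data would show (almost every extracted
AES covers a simulated GM), and passing tests demonstrate that the
rules are implemented exactly and behave monotonically — not that the
clinical concordance percentages transfer.

Artifacts are recorded as ground truth but leave the HR untouched by
default — exclusion is the evaluator's job; `artifact_mode="perturb"`
injects spikes so that tests can confirm masking actually protects the
metrics. A fixed seed reproduces a recording bit for bit; replicate
runs derive independent sub-seeds from one master seed.

`run_scenario` simulates replicates, extracts at each configured
threshold and pools the concordance — the scaffold for
threshold-comparison tables on synthetic data. One observed synthetic
behaviour worth naming: with GMs up to 120 s, the %dHR excursion decays
mid-episode (the moving average catches up), so long GMs often outlast
their AES and the full-course fraction sits well below the short-GM
case. The trapezoid profile's plateau is the cause; clinical GMs wax
and wane instead.

## Numerical choices

Window means use per-window summation (not running-sum differences), so
a window's mean is independent of where the series was sliced; feature
values on a slice equal the full-series values wherever the window
fits. Grid uniformity in CSV input is enforced to 1e-6 s. Sheet output
fixes 1 decimal for bpm columns and 2 for percentages and round-trips
losslessly at that precision. Undefined features are NaN in memory and
blank in CSV.

## Test design

The extraction path is verified against an independent brute-force
rule-follower (literal loops, coverage-component merging) on ~1000
random series spanning white-noise, random-walk and integer-plateau
regimes, at both thresholds and both flank conventions; rasterization
and the four metrics are verified against per-second membership
computation on random layouts. Acceptance-scale checks use 1800-s
recordings and 20-replicate scenarios, sizes at which every property
above is already exercised end to end.
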