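# Methods

## The phase model

An acute hypoxia test produces one SpO2/HR record per crew member with a
single canonical structure: supplemental-oxygen baseline, mask
disconnection at DM, progressive desaturation, reconnection at RM,
recovery. Six durations summarise the SpO2 curve — DT (= RM − DM), DeD
and HD (delays from DM to the first fall below the desaturation and
hypoxia thresholds), DeT and HT (total dwell time below each threshold),
and RT (delay from RM until the recovery threshold is reached again).

Every delay reduces to one primitive, `threshold_crossing_time`: the
time of the first sample beginning a run of at least `debounce`
consecutive samples satisfying the condition. Comparison semantics are
strict `< threshold` for the desaturation/hypoxia conditions and
inclusive `>= threshold` for recovery, reflecting that desaturation
means being *below* a level while recovery means *reaching* it. Whether
the boundary sample itself counts is a convention; the strict/inclusive
pair used here is documented and applied uniformly.

Dwell times (DeT/HT) integrate over the **whole record**, not just the
disconnection interval: a subject still below 97 % after reconnection is
still desaturated, and pre-disconnection dips count too. Each
sub-threshold sample contributes its local inter-sample interval; the
last sample contributes the nominal dt (median of successive
differences), which makes the sum robust to mildly irregular grids.
Missing samples contribute nothing and break debounce runs.

Records with several disconnection cycles are supported at the event
level (`detect_mask_intervals` reports every interval) but phase
parameters are computed from the **first** interval only, matching the
single-cycle training protocol; this is a deliberate simplification.

Censoring: DT and RT carry an explicit `censored` flag (with the
observed duration where meaningful) when the record ends before the
event; DeD/HD are `undefined` when the threshold is never crossed.
Censored values are excluded from group statistics and reported as a
separate count; range filters reject them unless `include_censored` is
set.

## Tunable parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `desat_threshold` | 97 | % SpO2 | anchors DeD, DeT |
| `hypoxia_threshold` | 90 | % SpO2 | anchors HD, HT |
| `recovery_threshold` | 97 | % SpO2 | anchors RT |
| `debounce` | 1 | samples | noise immunity of crossings |
| `max_gap` | 5 | s | continuity check |
| `response_drop` | 2 | % SpO2 | minimum post-DM fall for validity |
| `response_window` | 120 | s | window for the above |

The 97/90 % thresholds are the standard definitions for this test. The
default debounce of 1 keeps the crossing primitive exactly equivalent to
a naive per-sample scan; users with noisy oximeters should raise it
(the test suite demonstrates debounce 3 against 1 % Gaussian noise).
`response_drop`/`response_window` encode the expectation that a real
subject visibly desaturates within two minutes of disconnection; a flat
trace despite a recorded disconnection indicates a detached sensor or a
mask-event logging fault.

## Slopes and summaries

Segment slopes are ordinary least squares over all non-missing samples
in a closed time window, reported per minute (the physiological
convention for desaturation rates). r² is defined as 1 whenever
residuals vanish, including the zero-variance constant trace; a
degenerate constant window short-circuits to slope 0 exactly. Automatic
segmentation is phase-anchored — baseline [start, DM], desaturation
[DM, SpO2 minimum within the disconnection interval], recovery
[RM, RM + RT] — because the phase events are the only landmarks the
protocol guarantees; windows with undefined endpoints are skipped, and a
manual `fit_segment_slope` call with the same window semantics overrides
any automatic segment.

Group analysis aligns subjects at DM = 0 by default (the
post-disconnection response is the phenomenon of interest; record-start
anchoring is available), linearly interpolates onto a uniform grid whose
points are integer multiples of `dt_out`, and computes per-timepoint
statistics over pairwise-available data with `n_per_timepoint` exposed
for auditability. SD is the n−1 sample standard deviation, defined as 0
for a single contributor; quantiles use the linear-interpolation
convention throughout. Heat maps are a thin rendering layer over the
aligned matrix (SpO2 colour scale fixed at [60, 100] %, spanning
baseline to the deepest expected nadir); all tests target the numeric
matrix, never pixels.

## Synthetic records

The generator emulates the acquisition chain's output: baseline SpO2
97.5–99 %, a lag of a few seconds after DM (circulatory transit), an
exponential decline toward a nadir near 60 % — the typical saturation
floor during 25,000 ft exposures — exponential recovery after RM, and a
heart-rate channel mirroring the desaturation with a sympathetic rise.
Defaults: 600 s record at 1 Hz, DM = 60 s, RM = 360 s, baseline 98 %,
nadir 60 %, decline time constant 60 s, recovery time constant 15 s, HR
70 → +40 bpm, 1 % SpO2 noise, 2 bpm HR noise, 0.5 % sample dropout.
Exponential kinetics were chosen because they are smooth, monotone and
analytically invertible; real desaturation onsets are more nearly
sigmoid, and real noise includes motion artifacts and oximeter-accuracy
bias (worst below 80 % saturation) that are *not* modelled. Passing
tests therefore demonstrate correctness of the phase arithmetic and
robustness to additive noise and dropouts, not validation against
clinical recordings.

Ground-truth phases are obtained by inverting the exponential crossings
in closed form and snapping to the sample grid, before noise and
dropouts. Emitted SpO2/HR are quantized to whole units (oximeters report
integers); an integer reading crosses an integer threshold c exactly
where the continuous signal crosses ceil(c) − 0.5, so the inversion uses
that effective threshold and the ground truth describes the record
actually emitted. On noiseless draws the pipeline recovers every defined
phase within one sampling interval (exactly, in practice).

Flights draw per-subject parameters from independent spawned seed
streams, so the first k subjects are identical regardless of crew size;
DM/RM are shared across the crew because the protocol disconnects
everyone together.

## Numerical and design choices

- Files store floats via `repr`, the shortest exact round-trip form, so
  write→read→write is byte-identical.
- Channel alignment at ingestion: all channels share the CSV's time
  column; missing mask cells are filled by previous-value hold (the mask
  is a step signal), missing vitals stay missing (NaN internally, never
  a sentinel value).
- Filters combine by conjunction; the "valid" flight type is
  operationalised through the automatic validity check, with a manual
  per-subject override honoured when present in metadata. Other flight
  types are opaque labels matched case-insensitively.
- The phase-ordering invariants (DeD ≤ HD, HT ≤ DeT) are enforced only
  when thresholds are canonically ordered (hypoxia below desaturation).
- Problem sizes in the test suite and acceptance script (100 random
  traces, 100 noiseless subjects, 200 noisy draws, cohorts of 3–10) are
  chosen to exercise every branch while keeping the whole suite under a
  few seconds.

## Known limitations

- No oximeter accuracy correction: readings are taken at face value even
  though accuracy degrades below 80 % saturation.
- No motion-artifact removal or HR-variability analysis.
- Multi-cycle protocols (repeated disconnections) get event detection
  but not per-cycle phase tables.
- The original acquisition system's binary files and serial protocol are
  out of scope; ingestion starts at the open CSV + JSON dialect.
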