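# Methods

## Data model

A *session* is one procedure's landmark stream: per frame (0-based, time
base `[i/fps, (i+1)/fps)`) and per hand, either all 21 keypoints of a
hand-pose detector or none. The absence of a hand's records at a frame is
*tracking loss*; an explicit record with `hand = none` is a *null
detection* — the detector fired without resolving handedness, and the
record carries no landmark id or coordinates. This split matters because
detection performance (records over the 42-slot-per-frame maximum) and the
null share (null records over all records) are separate quantities: a 14%
tracking-loss rate coexists with a 0.1% null share. Coordinates are pixels
with origin at the top-left and y increasing downward, so reaches toward
the microscope handles approach y = 0; files store them at two decimals,
below detector jitter, which makes write→read round-trips bit-exact.

`fps` is required session metadata with default 30 — the rate under which
the per-procedure detection-performance accounting closes against record
counts for 600 s procedures (e.g. 621 898 / (600·30·42) = 82.26 → 82.2).

## Grid and occupancy

The calibration grid splits the frame into equal thirds by default —
the only parameter-free choice — with explicit edge overrides for scenes
whose gridlines were drawn to landmarks rather than thirds. Cells are
numbered 1–9 row-major. Bins are half-open, with the right/bottom frame
edge folded into the last column/row, so every in-frame point lies in
exactly one cell (tested exhaustively). Occupancy uses landmark 12 (middle
fingertip) by default; the landmark is a parameter, since any stable
keypoint serves as a cell proxy.

## Detection accounting and display convention

All rates are kept at full precision internally. Reported values are
truncated (floored) at display precision: truncation is the unique
convention under which every detection-performance and hand-share figure
closes against its raw counts (51.72 → 51.7, 49.49 → 49.4, 84.87 → 84.8,
1082.69 → 1082). The null share is the one exception — at 0.05–0.1% it sits
at the display resolution itself, and is rounded so a nonzero null count
never displays as 0.0. Dwell time per cell sums both hands, so per-cell
totals are bounded by 2 × duration; cross-procedure aggregation uses the
arithmetic mean and the sample SD (n−1), which requires at least two
procedures. Conservation — per-cell dwell plus per-hand undetected time
equals 2 × duration — is exact in frame counts by construction; the
seconds-level identity holds to float addition error (< 10⁻⁹ s).

## Event segmentation

Events are defined from cell occupancy rather than raw coordinate-spike
thresholds: excursions to known scene cells are what the spikes in
horizontal/vertical tracking plots depict, and cell semantics make
classification parameter-light. The algorithm: (1) UNDETECTED runs shorter
than `gap_fill_s` (default 0.5 s) are bridged with the preceding cell, so
single-frame glare dropouts do not fragment an excursion; (2) maximal runs
outside the center cell become candidate events; (3) each is classified
from the set of cells visited with precedence microscope > instrument >
trash > other, because a reach to the handles necessarily sweeps
intermediate cells; (4) adjacent same-kind runs separated by less than
`merge_gap_s` (default 1.0 s) merge; (5) events shorter than
`min_duration_s` (default 0.5 s) are dropped as blips. Events are disjoint
and time-ordered, and identical inputs give identical output.

Ordering merges before the duration filter is deliberate: a fragmented but
real excursion should survive. A consequence is that widening the merge gap
can *promote* two sub-threshold fragments into one reportable event, so
event count is monotone in the merge gap only with the blip filter off;
count is unconditionally monotone (non-increasing) in `min_duration_s`.

Ground-truth matching is greedy one-to-one in time order, requiring kind
equality and interval overlap within a tolerance (default 1 s). Precision
is undefined (NaN) when nothing was detected, recall when the truth is
empty.

## Simulator

The generator emulates the statistical structure the analysis assumes, not
hand appearance. Per hand, a semi-Markov schedule alternates drilling
dwells in the center cell with excursions; dwells are lognormal — positive
and right-skewed, consistent with event-duration SDs comparable to their
means — parameterized by mean/SD with defaults: drilling 50 (20) s,
instrument changes 21.5 (12.4) s at cell 4 (probability 0.40 after a
drill), microscope adjustments 4.4 (5.7) s at a uniformly chosen top-row
cell (0.35), trash visits 5.5 (9.1) s at cell 7 (0.25). That yields roughly
four instrument changes and three to four microscope adjustments per 600 s
procedure — a plausible-regime choice, since inter-event rates are not
independently constrained. Dwell draws are floored (drill 5 s, excursions
1 s): an unfloored lognormal at the microscope parameters puts ~16% of
draws below the 0.5 s detectability threshold, and sub-second excursions
are not meaningful surgical actions. Schedules begin and end in drilling —
an excursion that would overflow the session is replaced by drilling to the
end — so scheduled events are never truncated into undetectable stubs. The
non-dominant hand drills throughout by default (configurable); the dominant
hand is the right by default.

Within a state the occupancy landmark follows a discretized
Ornstein–Uhlenbeck walk toward the state's anchor (the cell center, offset
laterally ±80 px so the two hands do not overlap):
`p_{t+1} = p_t + θ(anchor − p_t)Δt + σ√Δt·ε`, with θ = 8 s⁻¹ and
σ = 60 px·s^(−1/2). The stationary jitter (σ/√(2θ) ≈ 13 px) stands in for
drilling micro-motion; transitions between anchors complete in ~0.1–0.2 s,
well inside the event-boundary tolerance. The other 20 landmarks hang off a
fixed hand-shaped template (scale 80 px, mirrored for the left hand) with
2 px Gaussian jitter; coordinates are clipped to the frame and rounded to
two decimals at render time.

Tracking loss is Bernoulli per hand-frame: base rate `p0` plus an excess
`p1` inside a disc of radius 250 px at frame center, the minimal geometry
for glare from the microscope light. Defaults p0 = 0.08, p1 = 0.08 put
center-dwelling hands near 16% loss and the session near 86% overall
detection performance; the constant-rate calibration point p0 = 0.14,
p1 = 0 reproduces that operating regime exactly (in expectation,
1 − 0.14 = 86%, within binomial error of a 36 000-hand-frame session).
Null records are injected at 0.025 per frame, giving a ~0.1% null share at
86% performance. All randomness flows from one integer seed
(`numpy.random.default_rng`; batches spawn child seeds via `SeedSequence`),
so sessions are byte-identical under a fixed seed.

### What the simulator does and does not capture

It reproduces: dwell-dominated center-cell behaviour, excursion events with
realistic duration spreads, center-weighted tracking loss, null records,
and exact ground truth for recovery tests. It does not capture: hand
kinematics beyond a smooth mean-reverting point process (no ballistic
velocity profiles, no bimanual coordination), detector failure modes that
correlate across frames (occlusion episodes), perspective or camera motion,
or real anatomy-driven workflow timing. Passing recovery tests therefore
demonstrates that the analysis inverts the generative model it assumes —
not that the event segmenter is validated on real operating-room video.

## Numerical and degenerate-input choices

- Truncation uses `floor(x·10^d)/10^d`; values are computed as exact count
  ratios so the floor is stable.
- Empty sessions: detection performance 0.0 over a nonzero frame count;
  hand shares and detections/second raise on zero denominators; zero-frame
  metadata is rejected at construction.
- `CellSeries` length always equals `n_frames` regardless of dropout;
  out-of-frame landmark positions are folded into UNDETECTED.
- Event boundaries: an event's end time is the end of its last frame's
  interval, so duration = (end_frame − start_frame + 1)/fps.
- Sample SDs use the n−1 denominator and are NaN (flagged) below two
  observations rather than zero.

## Known limitations

- A trash reach can graze the instrument-table cell's corner in transit;
  under the classification precedence that excursion escalates to an
  instrument change. At default kinematics this affects on the order of
  0.1% of excursions — a genuine ambiguity of cell-semantic classification,
  visible in recovery precision on unlucky seeds.
- The per-procedure *null* percentages printed in some published summary
  tables are tenfold larger than their own counts imply; only the
  arithmetically consistent cells are used as closure checks.
- Real per-cell dwell magnitudes and event durations from the original
  recordings are not reproducible without the videos; the suite covers them
  with conservation/recovery properties and a default regime that matches
  the qualitative dwell ranking (center dominant, instrument table second).

## Problem sizes used in tests

Unit and property tests run on 10–120 s sessions; conservation is checked
on six 120 s sessions (it is duration-invariant and exact in frames); event
recovery on twenty 600 s sessions at 5% dropout; dropout calibration and
the default-regime heatmap on full 600 s procedures — the package's choice
of a desk-scale replica of a three-procedure, 10-minute-each study design.
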