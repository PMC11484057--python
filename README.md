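# handmotion

Grid-occupancy analytics for 21-landmark bimanual hand tracking of
microsurgical procedures.

Video-based hand-pose detectors emit, for every frame of a procedure
recording, up to 21 keypoints per hand (wrist and digit joints) as pixel
coordinates — no physical sensors on the surgeon's hands. `handmotion` turns
those landmark streams into surgical-workflow analytics for the setting
where the camera faces the surgeon across a calibrated scene: a 3×3 grid
over the frame whose cells carry semantics — the surgical field in the
center cell (5), the instrument table middle-left (4), the microscope
handles across the top row (1–3), the trash bin bottom-left (7), and a
picture-in-picture microsurgical feed bottom-right (9).

The package computes:

- **Detection accounting** — detection performance
  `100 · n_records / (n_frames · 42)` (21 landmarks × 2 hands per frame),
  per-hand and null-detection shares, and detections per second. Reported
  values are *truncated* at display precision (the convention under which
  the accounting closes against printed summary counts); the null share is
  rounded so a nonzero null count never displays as zero.
- **Dwell times** — seconds each hand's occupancy landmark (landmark 12,
  the middle fingertip, by default) spends in each grid cell, summed over
  both hands, with cross-procedure mean (SD) and a 3×3 heatmap.
- **Workflow events** — instrument changes, microscope adjustments and
  trash visits segmented from occupancy excursions out of the center cell
  (gap-fill → run extraction → same-kind merge → minimum-duration filter),
  with per-kind duration statistics and validation against ground truth.
- **A behaviour simulator** — a semi-Markov surgeon model (lognormal state
  dwells, mean-reverting Ornstein–Uhlenbeck trajectories, a brightness
  dropout disc at frame center, null-handedness records) that generates
  full sessions *plus* ground truth, so every pipeline stage is testable
  without video.

## Worked example

```python
import handmotion as hm

config = hm.SimConfig()          # 600 s procedure, 30 fps, 1920x1080 frame
session, truth = hm.simulate_session(config, seed=5, procedure_id="demo")
grid = hm.make_grid(1920, 1080)

print("performance:", hm.detection_performance(session), "%")
print("shares (right, left, null):", hm.hand_shares(session))

left = hm.cell_series(session, grid, hm.HAND_LEFT)
right = hm.cell_series(session, grid, hm.HAND_RIGHT)
dwell = hm.dwell_times(left, right, session.meta)
print({c: round(v, 1) for c, v in dwell.items() if v > 0})

events = hm.detect_events(right, session.meta)
for ev in events:
    print(f"{ev.kind.value:18s} {ev.start_s:7.2f} -> {ev.end_s:7.2f}")
m = hm.match_events(events, truth)
print("precision", m.precision, "recall", m.recall)
```

prints

```
performance: 84.8 %
shares (right, left, null): (50.3, 49.6, 0.1)
{1: 3.4, 2: 5.4, 3: 5.7, 4: 43.8, 5: 955.2, 6: 0.1, 7: 3.7, 8: 0.1}
trash                34.17 ->   36.30
instrument_change    90.93 ->  110.60
instrument_change   148.20 ->  175.97
microscope_adjust   263.17 ->  264.10
trash               350.13 ->  351.10
microscope_adjust   396.07 ->  397.50
microscope_adjust   435.97 ->  440.63
microscope_adjust   477.60 ->  483.80
trash               508.40 ->  509.40
microscope_adjust   552.83 ->  555.53
precision 1.0 recall 1.0
```

Reading: with the default dropout model the detector captured 84.8% of the
possible landmark records, split almost evenly between hands with 0.1% null
detections. The hands spent 955 of a possible 1200 cell-seconds in the
surgical field (cell 5), 44 s at the instrument table (cell 4), and the
segmenter recovered every scheduled excursion — two instrument changes,
five microscope adjustments and three trash visits — with exact
precision/recall against the simulator's ground truth.

The same pipeline runs from the shell:

```bash
handmotion simulate --seed 1 --n-procedures 3 --out-dir sessions/
handmotion analyze sessions/session_*.csv --out analysis.json --dwell-csv dwell.csv
handmotion events sessions/session_proc_1.csv --out-csv events.csv
handmotion report sessions/session_*.csv --out report.json --plots-dir plots/
```

Real detector output can be fed in as CSV/JSON session files (see
`handmotion.session` for the schema: meta header plus
`frame_index,hand,landmark_id,x_px,y_px` rows).

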