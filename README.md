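# circafish

Image-based locomotion quantification and circadian-rhythm analysis for
fish kept in multi-tank recording chambers, plus a ground-truthed
synthetic video generator used to validate every stage without any real
recordings.

Two independent quantification backends operate on the same videos:

* **pixel activity** — frame differencing: the number of pixels per tank
  whose intensity changes by more than a threshold between adjacent
  frames. Fast, robust, but unit-free and sensitive to background
  artifacts (an optional 3×3 median prefilter suppresses line artifacts).
* **tracking** — background subtraction, blob detection and
  proximity-based linking produce per-fish trajectories, from which
  locomotion endpoints are computed: total distance, average speed,
  average angular velocity, meandering (deg/cm), freezing/swimming/rapid
  time ratios, and sleep bouts (quiescence strictly longer than 5 s).

Per-interval metrics are assembled into light/dark-labeled circadian
profiles and compared with min–max normalization (0–100 %), Spearman rank
correlation (exact permutation p for n ≤ 8), Welch's unpaired t-test, and
many-to-one (Dunnett-style) comparisons with a seeded Monte-Carlo
family-wise adjustment.

## CLI

```sh
# generate a 24 h synthetic study (1-min video per hour, 6 tanks x 3 fish)
simulate --profile diurnal --hours 24 --tanks 6 --fish 3 --seed 7 --out fixture/

# backend 1: frame-differencing activity
pixelact --video fixture/hour_00.tif --fps 30 --config cfg.toml --threshold 20 --out activity.csv

# backend 2: trajectories, then kinematics endpoints
track --video fixture/hour_00.tif --fps 30 --config cfg.toml --out traj.csv
kinematics --traj traj.csv --fps 30 --out kin.csv

# circadian profiles + statistics from per-interval tables
circadian --kin kin_intervals.csv --activity act_intervals.csv --config cfg.toml --out results/
```

The TOML config holds the tank layout (pixel ROIs + px/cm calibration,
which has no default and must be measured for each rig), the light
schedule and analysis thresholds; `simulate` writes a ready-made
`fixture_config.toml` alongside its videos. Coordinate conventions: pixel
origin at top-left, x right / y down, half-open ROIs; calibrated
trajectories are in cm relative to their tank's top-left corner.

## Known limitations

* Linking is proximity-only; identity may swap when fish pass within the
  linking radius. Tank-level aggregates are unaffected.
* A background estimated from a single clip absorbs any fish that rests
  through the whole clip; for circadian studies supply
  `track_video(..., background=...)` pooled across intervals (the
  `pipeline.run_study` helper does this automatically).
* Only uncompressed 8-bit/24-bit DIB AVI streams are supported; compressed
  codecs are rejected with a format error.
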