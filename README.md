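# steerflow

Analysis of intermittent human steering control with retinal optic flow:

- **ballistic** — Gaussian ballistic steering corrections: velocity/position
  profiles, superposition, onset/offset (`mu ∓ 2 sigma`), travel distance
  (`a·sigma·sqrt(2π)`) and coverage fractions.
- **decompose** — identification of the constituent corrections in an
  observed steering-rate signal by particle swarm optimization of an
  order-penalized L1 fitness (`max(N,1)^α / (t1−t0) · ∫|z − model|`), with
  exhaustive order selection, deterministic local polish and backward
  elimination.
- **flow** — retinal optic flow reconstruction (`v_r(p) = v(p) − v(p_g)`,
  zero flow at the fovea), full-quadrant flow directions, the lane-masked
  spatial circular-mean flow angle, gaze validity filtering (confidence ≥
  0.6, central 60 % of the screen), camera-tilt removal by the circular
  median over straight sections, and gaze headway metrics.
- **driving** — track geometry (arc-length parameterized S-track), heading
  deviation, lateral displacement/velocity, curve lateral acceleration,
  region-of-interest extraction, trial success/failure classification and
  summary tables, log-normal fits of absolute correction angles.
- **latency** — stimulus-to-correction response times: per-correction travel
  angles paired with a lagged cue and scanned with zero-normalized
  cross-correlation (Pearson) over τ ∈ [0, 2] s; Spearman/Kendall
  alternatives, per-curve angular recentering, pseudo-Huber robust linear
  regression.
- **synthetic** — everything with ground truth: S-track builder (60 m curve
  diameter), a kinematic single-track vehicle under an intermittent
  evidence-accumulation driver with injected response latency, a
  smooth-pursuit gaze model (pursuit gain 1.0, headway 4–25 m), an analytic
  dense ground-plane optic-flow renderer with exact lane masks, camera-tilt
  injection, and controlled stimulus→response generators for latency
  recovery studies.
- **pipeline / cli** — staged orchestration with TOML configuration, seeded
  reproducibility and a Markdown + JSON report.

## CLI

```sh
# full pipeline into a run directory
steerflow run-all --seed 7 --out-dir run1/ [--config config.toml]

# individual stages against the same run directory
steerflow simulate  --seed 7 --out-dir run1/
steerflow flowangle --seed 7 --out-dir run1/
steerflow decompose-stage --seed 7 --out-dir run1/
steerflow latency-stage   --seed 7 --out-dir run1/
steerflow report          --seed 7 --out-dir run1/

# file-level operations
steerflow decompose --input steering.csv --config config.toml --seed 17 \
    --out corrections.csv
steerflow latency --corrections corrections.csv --cue rof_angle.csv \
    --cue-name theta_rof --grid-step 0.0111 --out scan.csv
```

The TOML configuration mirrors `steerflow.pipeline.PipelineConfig`, with
`[driver]`, `[camera]` and `[pso]` tables (see
`tests/test_pipeline_cli.py::TestConfig::test_from_toml` for an example).
Reruns with the same seed and configuration are bit-identical.

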