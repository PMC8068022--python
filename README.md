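# gripsig

Analysis pipeline for multi-sensel pressure-glove recordings of hand
grasping: how the grip force (GF) is shared among 18 anatomical hand regions
while subjects perform activities of daily living.

The package covers the full chain:

1. **core_io** — data model for the 361-sensel / 18-region sensor layout and
   per-recording pressure matrices (T × 361, kPa, 50 Hz), with a plain
   CSV + JSON-sidecar on-disk format and strict validation.
2. **synthetic_data** — a study-shaped cohort generator (subjects × tasks)
   with analytic ground truth: parametric GF profiles, per-region
   contribution weights, subject amplitude/pace effects, sensor noise,
   single-frame spikes and saturation clipping at 517 kPa.
3. **preprocessing** — width-3 running-median despiking, whole-recording
   discard of saturated sensels, pressure→force conversion (16 mm² per
   sensel), region/GF aggregation, normalized-time resampling (101-point
   grid) and zero-phase 3rd-order Butterworth low-pass (10 Hz) filtering.
4. **synchronization** — cross-subject alignment with a bounded three-segment
   piecewise-linear time warp (knots t1, t1ref ∈ [0.15, 0.35]; t2, t2ref ∈
   [0.65, 0.85]); reference subject chosen nearest the cohort mean; cost is
   the Euclidean distance between first derivatives. Default optimizer is an
   exhaustive deterministic lattice search (resolution 0.01); a seeded
   differential-evolution strategy is available.
5. **contribution_analysis** — mean-GF scaling to the reference subject,
   outlier discard (4 farthest curves), mean ± SD task curves, per-region
   contribution-to-grip-force (CGF) over the above-mean-GF window,
   task/region Pearson correlation matrices, peak force/pressure tables and
   task-duration boxplot statistics.
6. **stats** — closed-form balanced ANOVA: additive two-way
   (subject × task, one observation per cell) and one-way (e.g. sex).
7. **signature_report** — per-task tactile-signature opposition graphs
   (circle radius ∝ CGF; edges connect finger regions to thumb/palm regions
   when both exceed 5%) rendered as deterministic SVG, plus the end-to-end
   pipeline orchestrator.

## CLI

```sh
# generate a synthetic study with known ground truth
gripsig simulate --config cfg.yaml --out data/ --seed 1

# clean recordings (median despike + saturation discard)
gripsig preprocess --in data/ --out clean/

# synchronize one task across subjects
gripsig sync --in data/ --task 3 --out sync/ [--strategy grid|stochastic]

# full analysis: sync, scaling, outliers, CGF, correlations, peaks, ANOVA,
# signature SVGs
gripsig analyze --in data/ --out results/ [--n-discard 4] [--threshold 0.05]

# ANOVA tables / per-task sex test on unscaled mean GF
gripsig stats --in data/ --out anova.csv [--sex-test]

# everything from a single YAML config
gripsig report --config report.yaml
```

A `simulate` config YAML takes `SyntheticConfig` fields
(`n_subjects`, `n_tasks`, `noise_sd_kPa`, `spike_rate`, `duration_mean_s`,
…); a `report` config takes `input_dir` (or an inline `simulate:` block),
`output_dir` and an `options:` mapping passed to the pipeline.

## Data formats

- recording CSV: header `time_s,s001,…,s361`, one row per frame, kPa;
- sidecar JSON: `subject_id`, `task_id`, `sample_rate_hz`, optional `sex`,
  `notes`;
- layout JSON: `regions` array (`id`, `label`, `class`, `sensel_ids`,
  `render_xy`) plus geometry constants; the packaged default is in
  `src/gripsig/data/layout_default.json`.
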