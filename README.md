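# quadgait

Stride-level gait analysis for quadrupeds filmed from above. The package
turns per-trial footfall events (limb, touchdown frame, liftoff frame) and
nose/tail-base landmark trajectories into five per-stride performance
measures — speed, stride length, stride frequency, mean support number, and
a sway (path-straightness) index — and runs the longitudinal statistical
layer on per-mouse daily averages: a gender × treatment-day linear
mixed-effects ANCOVA with random mouse intercepts, male-only speed-adjusted
partial regressions, rank-based Welch t-tests, and dopamine percent-change
arithmetic. A synthetic gait generator produces full studies with known
ground truth so the whole pipeline is testable without any real recordings.

## Layout

| module | what it does |
|---|---|
| `quadgait.simulate` | synthetic footfall events, landmark tracks, and full cohort-staggered studies with linear-in-day treatment effects, per-mouse random intercepts, and stride-to-stride noise |
| `quadgait.kinematics` | quintic smoothing splines (per-coordinate SSE tolerance, default 1 mm²), COM proxy at a fixed fraction of the nose-to-tail vector (0.415 male / 0.455 female), trunk-length CV, path length |
| `quadgait.strides` | stride segmentation at reference-limb touchdowns, limb phases, symmetrical/asymmetrical classification, event-based support-count timelines |
| `quadgait.metrics` | the five per-stride measures plus support percentages; enforces the speed ≡ length × frequency and duty-factor identities |
| `quadgait.stats` | daily averaging, mixed-effects ANCOVA (REML, containment df), speed-adjusted partial regression, rank-based Welch test, dopamine percent change |
| `quadgait.io` / `quadgait.cli` | CSV schemas with strict validation, YAML config, provenance sidecars, and the command line |

## CLI

```sh
# synthesize a study (contacts.csv, landmarks.csv, metadata.csv, ground_truth.json)
quadgait simulate --seed 1 --out-dir out/sim

# per-stride metrics (strides.csv, metrics.csv)
quadgait metrics --contacts out/sim/contacts.csv --landmarks out/sim/landmarks.csv \
    --metadata out/sim/metadata.csv --out-dir out/metrics

# daily averages + ANCOVA / speed-adjusted tables (daily.csv, results.json, tables.txt)
quadgait analyze --metrics out/metrics/metrics.csv --metadata out/sim/metadata.csv \
    --out-dir out/analysis

# text summary + per-gender trend plots
quadgait report --daily out/analysis/daily.csv --out-dir out/report
```

All knobs (COM fractions, spline tolerance, symmetry tolerance ε, minimum
sway displacement, reference limb, baseline day coding, simulation effect
model) live in a YAML config passed with `--config`; every output directory
gets a `provenance.json` with the config digest and seed.

## Conventions

Frames are 0-based integers; contact intervals and stride windows are
half-open (`[touchdown, liftoff)`, `[td_k, td_{k+1})`). Positions are in cm
in the trackway frame (pixel inputs are converted once at read time via each
trial's `px_to_cm`). Baseline is coded day 0 and day is a continuous
covariate in all models.
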