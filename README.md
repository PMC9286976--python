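# climbkit

Analysis toolkit for multibeam vertical-tube climbing assays in
*Drosophila*. A MultiBeam activity monitor records each fly's position in a
vertical tube (51 mm detection zone, 3 mm increments → 17 positions) once
per second for a 20-minute assay. climbkit turns those recordings into
per-fly climbing metrics, classifies descents as drops vs descending
climbs, simulates synthetic cohorts with ground-truth event logs, and runs
the group statistics used in climbing, flight, and delayed-treatment
("therapeutic window") experiments.

## Modules

| Module | What it does |
| --- | --- |
| `climbkit.monitor_io` | Read/write monitor exports and canonical trajectory & flight tables; gap policy (hold-last, flag gaps > 5 s) |
| `climbkit.kinematics` | Geometry, position→height mapping, movements, section dwell times |
| `climbkit.climb_metrics` | Climbing-event segmentation and the per-fly metric vector (climbs to top, avg/total height climbed, peak height, complete ascents, dwell, movements, velocities) |
| `climbkit.descent_classifier` | Descent segmentation; drop (> 8.97 mm/s) vs descending climb (< 6 mm/s) with a strict > 3 mm distance floor |
| `climbkit.fly_simulator` | Semi-Markov behavioral simulator, 1 Hz sampling + 3 mm quantization, phenotype presets, ground-truth logs |
| `climbkit.group_stats` | Two-way ANOVA + Tukey HSD, Fisher exact, Marascuilo multiple-proportion procedure with Bonferroni correction, treatment-window analysis |
| `climbkit.cli` | `climbkit` command-line pipeline |

## CLI

```bash
# simulate two demo cohorts and analyze them
climbkit simulate -o out/ --seed 1
climbkit metrics  -i out/trajectories.tsv -o out/metrics.tsv
climbkit classify -i out/trajectories.tsv -o out/descents.tsv --summary out/summary.tsv
climbkit stats    --metrics out/metrics.tsv --response n_climbs_to_top -o out/report

# flight proportions (Marascuilo with a designated control, or window analysis)
climbkit flight --table flight.tsv --control 0.0 -o out/pairs.tsv
climbkit flight --table flight.tsv --analysis window -o out/window.tsv

# full synthetic walkthrough
climbkit demo -o demo/ --seed 1
```

Geometry and classifier thresholds can be overridden with `--config
config.yaml` (keys `geometry:` and `classifier:`); all randomness flows
from `--seed`.

## File formats

Canonical trajectory table (TSV): `fly_id, t_s, height_mm, genotype,
age_days, dose_ug_per_ml, start_day` — one row per fly-second.

Multibeam export dialect (TSV, `#` comments allowed): `t_s, tube,
position` with positions 1–17; an optional YAML manifest maps tube ids to
fly metadata. See `climbkit/monitor_io.py` for the annotated layout.

Flight table (TSV/CSV): `fly_id, genotype, dose_ug_per_ml, start_day,
flew` with `flew` in `{0,1,yes,no,true,false}`.

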