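# pedflow

Discrete-event simulation and analysis of patient flow in a pediatric
emergency department (PED), built around a *secondary triage* prioritization
policy: after initial acuity triage, pending actions (triage of new patients,
first evaluations, blood draws, result reviews, specialist consults,
treatments, the final senior decision) are ranked dynamically using each
patient's length of stay relative to reason-specific P50/P75/P95 reference
percentiles. A standard acuity-then-arrival dashboard policy is provided as
the baseline, and a day-randomized two-arm trial harness plus an analysis
pipeline (median/IQR summaries, priority-adjusted ANCOVA, standardized
differences, census-curve permutation tests) mirror a day-randomized
controlled evaluation of such a tool.

## Layout

| Module | Purpose |
|---|---|
| `pedflow.calibration` | Quantile-matched (zero-inflated) log-normal fits from printed median/IQR rows, transfer-latency model, LOS reference percentiles, default case mix and stage specs (shipped in `data/calibration.yaml`) |
| `pedflow.policy` | Status colors, stage-graph action enumeration, the secondary-triage and standard ranking policies, overcrowding mode |
| `pedflow.simulator` | Arrival process, patient generation, passthrough and mechanistic (resource-constrained) execution modes, event-log linter, trial randomization |
| `pedflow.analysis` | Interval extraction, summaries, census curves, stratified permutation test, ANCOVA, standardized differences, Little's-law planning arithmetic |
| `pedflow.sus` | System Usability Scale scoring, interpretation bands, Spearman correlation |
| `pedflow.io` / `pedflow.cli` | CSV/Config round-trips, run manifests, `pedflow` command line |

Simulation modes: **passthrough** (default) samples the calibrated stage
intervals directly — the published intervals already include waiting time, so
this mode is used for calibration checks; **mechanistic** runs a
resource-constrained event loop in which waits emerge from staff contention
and the chosen policy.

## CLI

```sh
pedflow simulate --seed 1 --days 2 --out run/            # one-arm simulation
pedflow trial --seed 7 --days 30 --out trial/            # randomized two-arm trial
pedflow analyze --log trial/events.csv --out report.json --md report.md
pedflow sus --responses responses.csv --out sus.json
pedflow report --analysis report.json --out report.md
```

Event logs are written as `events.csv` (`patient_id, day, arm, event,
t_minutes`) with a `profiles.csv` sidecar and a `manifest.json` recording the
config hash and seed; identical config + seed reproduce byte-identical
outputs. Configs are YAML key-value files (any subset of `SimConfig` fields);
an empty file yields the fully calibrated defaults (78 arrivals/day, 23%
overnight share, published case mix and stage intervals).

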