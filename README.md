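# wearcomply

A pipeline for assessing the feasibility and acceptability of minute-epoch
consumer-wearable data collection in small clinical cohorts. It covers five
stages:

- **synth** — simulate per-participant wearable streams (1-minute heart-rate
  and step epochs, nightly sleep logs with 30-second stage runs, sync events)
  for three groups (`acute-orthopedic`, `acute-cardiac`, `chronic-IIPT`) with
  group-specific wear propensities, bout-structured off-wrist episodes,
  charging gaps, clip-mode sensor dropout, and ~7-day on-device storage
  truncation. Ground-truth per-minute wear annotations are retained for
  oracle testing.
- **ingest** — parse the raw-export JSON dialect (see
  `docs/raw_export_dialect.md`) into validated records, reconcile 30-second
  sleep epochs with the 1-minute activity grid, and derive daily summaries
  and CSV interchange tables.
- **compliance** — infer per-minute wear (worn ⇔ heart rate present OR
  steps > 0), trim the first/last partial days and the first night, and
  classify day compliance (≥600 awake worn minutes per calendar day) and
  night compliance (≥180 consecutive worn minutes inside a logged sleep
  period), with per-participant and per-group aggregation.
- **monitor** — daily monitoring flags (no sync for 3 days, 2 consecutive
  noncompliant days) and a deterministic daily report plus `flags.csv`.
- **stats** — acceptability item summaries (0–10 scales), adverse-reaction
  rates, pooled-variance two-sample t tests (df = n1+n2−2; Welch behind a
  flag), Mann-Whitney U tests (midranks, exact p for small tie-free samples,
  tie-corrected normal approximation otherwise), and the full three-table
  reporting grid.

## CLI

```sh
wearcomply simulate --config cfg.yaml --seed 7 --out out/          # raw exports + ground truth
wearcomply ingest   --in out/raw --out out/tables                  # epoch + daily-summary CSVs
wearcomply score    --in out/raw --out out/scored \
                    --day-threshold 600 --night-threshold 180      # compliance CSVs + group_stats.json
wearcomply monitor  --in out/raw --as-of 2024-03-20 --out out/mon  # flags.csv + report_DATE.html
wearcomply stats    --in out/raw --out out/tables.json             # full reporting grid
```

`cfg.yaml` maps directly onto `wearcomply.synth.SimConfig`; per-group fields
accept a scalar or a mapping keyed by group label, e.g.

```yaml
seed: 7
n_per_group: {acute-orthopedic: 10, acute-cardiac: 24, chronic-IIPT: 28}
study_days: {acute-orthopedic: 20, acute-cardiac: 20, chronic-IIPT: 24}
wear_prob_day: {acute-orthopedic: 0.88, acute-cardiac: 0.78, chronic-IIPT: 0.93}
wear_model: bouts          # or "iid"
clip_mode_prob: 0.02
```

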