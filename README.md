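# steptrack

Analytics for remote activity monitoring of patients on cyclic treatment:
wear-day adherence classification, short-form symptom questionnaire
(MSAS-SF) scoring, day-over-day step-count volatility, and cohort-level
correlation/comparison analyses — plus a synthetic cohort generator so the
whole pipeline is testable without any external data.

## Timeline conventions

Study days are integers relative to the first treatment administration
(day 0). The baseline ("pre") window is days −7..−1, the follow-up
("post") window days 1..14; day 0 belongs to neither window. A study day
is **full** when more than 100 steps were recorded, **partial** when a
count of at most 100 was recorded (0 included), and **none** when there
is no recording. A patient is **adequate** when both windows contain at
least three full days.

### A note on printed percentages

Completeness percentages are reported as integers: `pct_partial` and
`pct_none` are rounded half-up from the raw percentages, and `pct_full`
is their complement to 100, so the three figures always total 100. This
matches the convention of the published counts this package reproduces
(195/280 full days printed as 69%, 83/280 no-data days as 30%); no single
nearest-integer rule yields both of those figures at once.

## Library overview

| module | contents |
| --- | --- |
| `steptrack.cohort` | `StepSeries`, `PatientMeta`, `Cohort`; CSV readers/writers (absent days round-trip as empty fields, distinct from 0-step days) |
| `steptrack.adherence` | `classify_day`, `is_adequate`, `filter_cohort`, `completeness_report` |
| `steptrack.msas` | 32-item catalog, `score_msas` (GDI / PHYS / PSYCH / TMSAS subscale means with ≥50% proration), `msas_improvement` |
| `steptrack.volatility` | `daily_volatility` (relative change over strictly consecutive recorded days), `annualized_volatility` (sample SD × √365), `direction_day_counts`, `annualized_change_summary` |
| `steptrack.analysis` | full-day phase summaries, pre/post 4×4 Pearson correlation matrix, per-day correlation profiles, ECOG-group comparison (exact Mann-Whitney + Spearman), symptom-improvement splits, age splits |
| `steptrack.synthgen` | `SimConfig`, `gen_cohort`, named presets (`reference`, `null`, `high-dropout`) |
| `steptrack.reporting` | `run_pipeline` (read → filter → completeness → scoring → volatility → analyses → JSON/CSV/charts), chart renderers |

## CLI

```bash
steptrack simulate  --scenario reference --seed 7 --out simdir/
steptrack adherence --steps simdir/steps.csv --phase pre --out report.json
steptrack msas      --responses simdir/msas_pre.csv --out scores.csv
steptrack volatility --steps simdir/steps.csv --out volatility.csv
steptrack analyze   --in simdir/ --out results/
steptrack run       --config run.yaml        # same pipeline from a YAML config
```

`run.yaml` fields: `input_dir`, `out_dir`, `make_charts` (default true),
`age_threshold` (default 60), `log_level` (default INFO).

## File formats

* `steps.csv` — `patient_id,study_day,steps`; empty `steps` = no recording.
* `patients.csv` — `patient_id,ecog,age,sex,chemo_type`.
* `msas_pre.csv` / `msas_post.csv` — `patient_id` + 32 canonical item
  columns (snake_case; common synonym headers are accepted), integer
  values 0–4, empty = unanswered.
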