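# souvenir

Analysis pipeline for dual-wrist accelerometry collected during vibrotactile
cued-activity programs: raw wrist logs and cue-event logs in, wear-time
compliance, pre/post-cue activity response rates, user-experience survey
scores (SUS, QUEST, a 37-item intrinsic-motivation inventory), and cohort
statistics out. A seeded synthetic-data generator stands in for raw device
data, so every stage is testable end to end.

## Pipeline

1. **I/O + types** (`souvenir.types`, `souvenir.io`, `souvenir.config`) —
   accelerometer/cue logs as header + CSV (timestamps in seconds since day
   start), session schedules (default: 8 h window, three 30 min sessions,
   one cue every 30 s = 180 cues/day), YAML configuration.
2. **Signal curation** (`souvenir.pipeline`) — synchronize/resample both
   wrists onto a common 12.5 Hz grid (linear interpolation, never across
   gaps), 0.25–2.5 Hz zero-phase Butterworth bandpass per contiguous
   segment, Euclidean-norm magnitude, 1 s epoch sums, thresholded binary
   activity counts.
3. **Adherence metrics** (`souvenir.adherence`) — non-wear gaps (holes
   ≥ 60 s between samples), wear-time compliance percentage, post-cue
   response rate (≥ 1 s of activity within 5 s after a cue) and pre-cue
   activity rate (same rule in the 5 s before), per-cue-index engagement
   curve.
4. **Survey scoring** (`souvenir.surveys`) — standard SUS 0–100 scoring,
   QUEST item mean + importance tally, intrinsic-motivation subscale means
   with config-driven subscale map and reverse items.
5. **Cohort statistics** (`souvenir.stats`) — one-sample threshold t tests
   (90% CI) and the paired pre/post test (95% CI), plus structured
   JSON/text report assembly.
6. **Synthetic data** (`souvenir.synth`) — seeded generator for single days
   and whole cohorts: gravity + sensor noise + movement bursts, per-cue
   Bernoulli responses with engagement decay, tiled background activity,
   wear gaps and dropouts, survey sheets, fixture directories.

## CLI

```sh
souvenir simulate --seed 7 --out-dir fixtures --participants 5 --days 2
souvenir process  --mi mi.csv --li li.csv --cues cues.csv --out epochs.csv
souvenir metrics  --fixture-dir fixtures --out-dir metrics
souvenir surveys  --sus fixtures/sus.csv --quest fixtures/quest.csv \
                  --imi fixtures/imi.csv --out scored.csv
souvenir report   --metrics-dir metrics --surveys-csv scored.csv --out-dir report
```

All subcommands take `--config <yaml>` (`schedule.session_starts` is the only
required key; everything else defaults to the standard protocol) and the
group takes `--log-level`. Exit codes: 0 ok, 1 usage error, 2 data error.

## Conventions worth knowing

- Epochs are 1 s, half-open, 0-based: epoch *k* covers [k, k+1) s.
- The post-cue window is the 5 epochs starting at `ceil(t_cue)`; the
  pre-cue window is the 5 epochs ending at `floor(t_cue)`.
- A gap of **exactly** 60 s counts as non-wear; 59.9 s does not.
- The activity threshold (default 0.15 g·s per epoch) is a calibrated repo
  constant — the source analysis names a thresholding approach without
  printing a value (`souvenir.pipeline.calibrate_threshold` reproduces the
  calibration).
- The default intrinsic-motivation subscale map and reverse-item set are a
  documented convention (`souvenir.config`); verify against the administered
  instrument before comparing published subscale scores.
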