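# File formats

All files are UTF-8, comma-delimited CSVs with a header row.

## Fluency table (input)

One produced response per row, long format:

| column        | type    | meaning                                              |
|---------------|---------|------------------------------------------------------|
| `participant` | string  | opaque participant id                                |
| `trial`       | int     | trial index (1..3 in the standard design)            |
| `position`    | int     | order within the list, starting at 1 (optional: row order is used if absent) |
| `item`        | string  | the response as typed; normalized on read (lowercase, trimmed, whitespace collapsed) |
| `rt_ms`       | float   | inter-item latency in ms; for position 1, latency from trial start; empty = missing |

Other column names are mapped with a `Dialect` (e.g.
`Dialect(participant="subj", rt="latency")`).  A converter
(`cumulative_to_interitem`) turns cumulative within-trial timestamps into
inter-item latencies.  Every read attaches a report: rows read, lists
formed, rows rejected (non-numeric rt) with row-level messages, and
missing-rt counts — rows are never dropped silently.

## Category dictionary / lexicon (input)

| column     | type   | meaning                       |
|------------|--------|-------------------------------|
| `category` | string | category label (non-empty)    |
| `member`   | string | item; normalized like responses |

An item may appear under several categories; memberships are unioned.

## Coded table (audit export)

Per response: `participant, trial, position, item, rt_ms, categories`
(`;`-joined), `is_intrusion, is_perseveration, is_switch, cluster_id`
(global id; empty for invalid responses).

## MVT results

One row per scope unit (`mvt_group.csv`, `mvt_participant.csv`,
`mvt_trial.csv`): `scope, label, switch_time_mean_ms,
empirical_leave_mean_ms, optimal_leave_ms, abs_deviance_ms, rel_deviance,
max_rate_per_ms, n_clusters, n_switch_times`.

`retrieval_curve.csv`: `jump_time_ms, g` — the average retrieval curve as
(jump time, value) pairs; the curve is constant between jumps.

## Permutation outputs

`null_distribution.csv`: `perm, abs_deviance_ms` (one row per
permutation).  `null_summary.csv`: scope, permutation count, seed,
empirical deviance, null mean/min, and the exceedance (fraction of
permuted deviances at or below the empirical one).
`individual_test.csv`: per participant, empirical deviance, null
mean/min, and whether the empirical value beats the null mean;
`individual_summary.csv` adds the binomial summary.

## Exclusion report

`exclusions.csv`: one row per input list — `participant, trial, retained,
reason, n_valid_responses, n_intrusions`, with `reason` one of
`missing_rt, too_few_animals, intrusion_quota, incomplete_participant`
(empty when retained).

## Run metadata

Every output directory written by the pipeline contains
`run_metadata.yaml`: the configuration, the seed, package versions, and
the list of tables — enough to reproduce the directory exactly.

## Simulated studies

`semforage simulate` writes `fluency.csv` and `lexicon.csv` in the input
formats above plus `ground_truth.json`: the generator configuration, the
MVT solution (global rate, optimal leave count and residence time), and
per-participant records (age, latency scale, realized leave count).
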