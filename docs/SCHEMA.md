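# CSV schemas

All files are comma-separated UTF-8 with a mandatory header row; missing
values are empty fields. Times are days since egg collection.

## Inputs

### vials.csv
| column | type | meaning |
|---|---|---|
| vial_id | string | unique vial identifier |
| treatment | string | microbial treatment label |
| experiment_day | int 1–3 | which of the three time-staggered experiments |
| replicate | int | replicate vial index within the experiment |

### intervals.csv
One row per vial per twice-weekly interval; intervals must tile the
experiment without overlap and female counts must be conserved
(`females_at_start[i+1] = females_at_start[i] − female_deaths[i] −
females_censored[i]`).

| column | type | meaning |
|---|---|---|
| vial_id | string | parent vial |
| start_day | number | interval start |
| class_length_days | number | 3 or 4 under the twice-weekly design |
| laying_window_hours | number | egg-laying window opening the interval (default 18) |
| pupae_count | int ≥ 0 | F1 pupae formed from the window |
| females_at_start | int ≥ 0 | live P-generation females at window start |
| female_deaths | int ≥ 0 | deaths during the interval |
| females_censored | int ≥ 0 | flies lost during transfers |

### contamination.csv
| column | type | meaning |
|---|---|---|
| vial_id | string | vial checked |
| week | int ≥ 1 | week of the weekly CFU plating |
| cfu_per_fly | number ≥ 0 | CFU per fly of the observed colonies |
| unexpected_morphology | bool | colony morphology not matching the treatment |

### og_matrix.csv
`og_id` column plus one 0/1 column per strain (strain column names must
match treatment labels in fitness.csv for the association stage).

### annotations.csv (optional)
`og_id`, `annotation`.

## Outputs

### fitness.csv
`vial_id, treatment, experiment_day, replicate, lambda` — one row per
vial surviving the contamination filter; `lambda` is the dominant
eigenvalue of the vial's Leslie matrix.

### survival_records.csv
`vial_id, treatment, time_days, event` — one row per female;
event 1 = observed death, 0 = censored (lost or alive at the end).

### stats_summary.csv
`analysis, test, statistic, df, p, treatment, letters` — one row per
treatment per analysis; treatments sharing a letter are not significantly
different after correction.

### permutations.csv
`trait, class_index, factor, vial_id, treatment, lambda_observed,
lambda_permuted` — per-vial λ before and after scaling one age class's
survival or fecundity by `factor`.

### permutation_summary.csv
`trait, class_index, factor, rho, rho_p, kw_h, kw_p` — Spearman
correlation of observed vs permuted λ and the Kruskal–Wallis test across
treatments on permuted λ, per grid cell.

### mgwa_results.csv
`pdg_id, p_raw, p_bonferroni, beta, mean_fitness_present,
mean_fitness_absent, n_ogs, strains_present, member_ogs, testable,
annotations` — one row per phylogenetic distribution group, sorted by
raw p; `beta` is the presence effect on λ from the random-intercept
model; untestable (constant-presence) PDGs carry NaN statistics.

### provenance_<stage>.json
Stage name, full config, config SHA-256, seed and package version for
byte-identical reruns.
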