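# Packaged data files

## taxonomy.csv

Canonical activity taxonomy at fee-schedule granularity.

| column | meaning |
|---|---|
| `id` | short stable category identifier, used everywhere in the API |
| `display_name` | human-readable label as it appears on fee schedules |
| `group` | one of `hygiene_environment`, `family_health`, `disease_prevention`, `first_aid`, `ncd`, `group_training`, `non_billable` |
| `urban_billable` | 1 if the activity is billable for urban HEWs (12 categories) |
| `rural_billable` | 1 if the activity is billable for rural HEWs (14 categories) |
| `sort_order` | canonical fee-schedule row order; non-billable buckets sort last |

Voluntary HIV counseling/testing and TB services are in scope for rural
HEWs only. Enabling activities (travel, recordkeeping, training received,
idle time) are never billable; they carry no identifiable service user.

## synonyms.csv

Mapping from raw time-motion-study activity labels to taxonomy ids.
Matching is case-insensitive and whitespace-normalised; labels with no
entry raise an explicit error rather than being dropped. Extend this file
to support a new observation-log vocabulary without code changes.

## reference_urban.csv / reference_rural.csv

Published fee-schedule reference tables used (a) as printed inputs for the
rounded-cell chaining reproduction mode and (b) as the regression reference
for `compare_to_reference`.

| column | meaning |
|---|---|
| `pct_encounters` | percent of billable encounters in the setting |
| `mean_min`, `sd_min` | mean (SD) minutes per encounter after outlier exclusion |
| `base_birr`, `base_usd` | base salary cost per encounter |
| `cost82_birr`, `cost82_usd` | total cost at the 82% non-salary rate (management + overhead) |
| `cost270_birr`, `cost270_usd` | total cost at the 270% non-salary rate (supplies + management + overhead) |

US$ columns use 22 birr per US$. The rural group-training total at the 82%
rate is stored as 10.30 (two decimals; the source prints 10.3).

## Fee-schedule output files

`FeeSchedule.write_csv` emits the same columns as the reference tables plus
`display_name`, preceded by `#`-prefixed header lines holding the parameter
snapshot (salary, billable minutes, per-minute rates, multipliers, exchange
rate, mode) so every fee is auditable back to its inputs.
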