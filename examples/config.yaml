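# Annotated hewcost configuration.
#
# Every key is optional; omitted keys fall back to the published study
# conditions. Pass with `hewcost cost --config examples/config.yaml ...`
# or `hewcost simulate --config ...`.

# Fraction of the year HEWs spend on seasonal campaigns (measles/polio
# drives, in-service training, non-health mobilisation). Used by the
# default uplift formula u = 1/(1 - f) when no per-setting
# rate_uplifted_override is given.
campaign_fraction: 0.1742

# Birr per US$ for the US$ columns.
exchange_rate: 22.0

# Non-salary costs as fractions of salary cost. These explicit values
# are the default. Alternatively supply `cost_shares:` (salary,
# supplies, management, overhead as fractions of total program cost) to
# derive multipliers as p_x / p_salary — that path warns when the
# shares do not sum to 1.
multipliers:
  supplies: 1.88
  management: 0.33
  overhead: 0.49

# Per-setting cost inputs. salary_month / billable_min_month override
# values derived from the salary survey and observation log;
# rate_uplifted_override injects a campaign-adjusted per-minute rate
# verbatim (set it to null to use the uplift formula instead).
settings:
  urban:
    # salary_month: 1419
    # billable_min_month: 900
    rate_uplifted_override: 1.88
  rural:
    # salary_month: 1513
    # billable_min_month: 1600
    rate_uplifted_override: 1.25

# Synthetic-generator overrides for `hewcost simulate` (per setting).
# Defaults emulate the study: 22 workers/setting observed 21 days,
# published duration/mix targets, 7-Woreda salary survey.
generator:
  rural:
    n_workers: 22
    n_days: 21
    outlier_rate: 0.005
  urban:
    n_workers: 22
    n_days: 21
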