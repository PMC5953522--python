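# hewcost

Time-driven activity-based costing (TDABC) for Ethiopia's Health
Extension Program, for health-economics analysts and district (Woreda)
managers who need full-cost-recovery fee schedules for health extension
worker (HEW) services.

HEWs are salaried community health workers delivering primary care from
health posts. Routine administrative data rarely support costing their
services, so `hewcost` combines three inputs a manager can actually
obtain — a time-motion observation log, a Woreda salary survey, and
national program cost shares — into a per-encounter fee schedule for
each *billable* activity (one with an identifiable individual or
community user), separately for urban (12 activities) and rural (14
activities, adding HIV counseling/testing and TB services) settings.

## Model

Per setting, with salary `S` (birr/month) and observed billable minutes
per worker-month `M`:

```
r   = S / M                    salary per billable minute
r_u = r / (1 − f)              campaign uplift (fraction f of the year on campaigns)
b   = r_u · d̄                  base salary cost per encounter of mean duration d̄
fee = b · (1 + m)              m = non-salary multiplier (fractions of salary cost)
```

with `m = 2.70` for full cost (supplies 1.88 + management 0.33 +
overhead 0.49) or `m = 0.82` when supplies are donated, and US$ at 22
birr per US$. Encounter durations more than 3 SD above their category
mean (mean/SD from the full sample, single pass) are excluded before
`d̄` and `M` are computed. Money is rounded in exact decimal arithmetic,
half-up (birr to 1 decimal, US$ to 2). See `docs/methods.md` for the
full account.

## Worked example

```python
import hewcost as h

params = h.paper_parameters("rural")          # S=1513, M=1600, printed rate override
print(f"rural salary/min: {h.report_rate(params.rate_base):.2f} birr "
      f"(uplifted: {params.rate_uplifted:.2f} birr/min)")

sched = h.build_reference_schedule("rural")   # chained mode from printed inputs
tb = sched.line("tb_services")
print(f"TB services: base {tb.base_birr} birr (US${tb.base_usd}), "
      f"82% fee {tb.cost82_birr} birr, 270% fee {tb.cost270_birr} birr (US${tb.cost270_usd})")
print("discrepancies vs published table:", h.compare_to_reference(sched))
```

prints

```
rural salary/min: 0.94 birr (uplifted: 1.25 birr/min)
TB services: base 5.3 birr (US$0.24), 82% fee 9.6 birr, 270% fee 19.6 birr (US$0.89)
discrepancies vs published table: []
```

i.e. a rural HEW earns 0.94 birr per billable minute (1.25 after
accounting for time lost to seasonal campaigns); a 4.2-minute TB
encounter carries 5.3 birr of salary cost, and a fee of 19.6 birr
(US$0.89) recovers salary, supplies, management and overhead.

The same pipeline runs on your own data from the shell:

```
hewcost simulate --seed 7 --out sim/            # or bring your own log + survey
hewcost cost --log sim/observation_log_rural.csv \
             --survey sim/salary_survey_rural.csv --out fees/
```

which writes `fee_schedule_<setting>.csv` (with the full parameter
snapshot embedded for audit), a printable tally-style encounter form,
and a run manifest. Input formats, the activity taxonomy and the
raw-label synonym map are documented in
`src/hewcost/data/data_dictionary.md`; an annotated configuration
example is in `examples/config.yaml`.

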