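# Methods

## The costing model

`hewcost` implements time-driven activity-based costing (TDABC) for
Ethiopia's Health Extension Program. HEWs are salaried community health
workers; the question the package answers is what fee per client
encounter would recover the full program cost of each billable service,
separately for urban and rural HEWs (whose scopes of practice differ).

The chain, per setting:

1. **Salary input** `S` (birr/month): unweighted mean over Woredas of the
   per-Woreda salary midpoint `(low + high)/2`.
2. **Billable time** `M` (min/worker-month): total observed minutes on
   billable activities per worker, outlier-excluded, scaled to a 30-day
   month by `30 / days observed`, averaged over workers. The source data
   never state how a 21-day window maps to "per month"; 30 days is this
   package's convention.
3. **Base rate** `r = S / M` (birr/min).
4. **Campaign uplift**: HEWs lose a fraction `f` of the year to seasonal
   campaigns (measles/polio drives, in-service training, non-health
   mobilisation). A year's salary must be recovered from the remaining
   `(1 − f)` of billable time, so `r_u = r / (1 − f)`. The published
   per-minute rates (1.25 rural, 1.88 urban birr/min) are not consistent
   with any single uplift rule (the source prints f = 17.42% for 9
   weeks — arithmetically 17.31% — and describes a "31% increase" while
   its rates imply +33% and +20%), so `CostParameters` accepts an
   explicit `rate_uplifted_override`; reproduction runs inject the
   printed rates, analysis runs may use the formula.
5. **Base salary cost per encounter** `b = r_u · d̄`, with `d̄` the mean
   kept duration of the category's encounters.
6. **Total cost per encounter** `b · (1 + m)`, where `m` sums the
   non-salary components expressed as fractions of salary cost:
   supplies 1.88, management 0.33, overhead 0.49 — totals m = 2.70
   (full cost) and m = 0.82 (supplies donated). These explicit
   multipliers are canonical; deriving them from the national program
   cost shares (salary 27%, supplies 55%, management 9%, overhead 13%)
   is supported (`derive_multipliers`) but carries a warning, because the
   printed shares sum to 104% and give a supplies multiplier of 204%,
   not 188%. The self-consistent sums 188+33+49 = 270 and 33+49 = 82
   decide the conflict in favour of the explicit multipliers.
7. **Currency**: US$ = birr / e, default e = 22 birr per US$.

## Outlier exclusion

Encounters longer than `mean + 3·SD` of their category are excluded,
with mean and SD computed once on the full sample (no re-iteration).
The rule is one-sided by default: durations are bounded at zero, so for
the dispersions seen in this data no observation can lie 3 SD below a
positive mean; a `two_sided` switch exists for other data. SDs use the
sample (n−1) convention, with `ddof=0` available. A single observation
(SD undefined) is never excluded.

## Rounding

Money arithmetic that feeds reported cells runs in exact decimal:
birr half-up to 1 decimal, US$ half-up to 2. Binary floating point
mis-rounds exactly the cells that matter (124.5 × 3.7 = 460.6499…
instead of 460.65 → 460.7). Two computation modes exist:

* **unrounded** (analysis default): unrounded values propagate through
  the whole chain; rounding happens only at report fields.
* **chained** (reproduction): each cell is recomputed from the rounded
  upstream cell — totals from the rounded base birr, US$ from rounded
  birr — matching how published tables chain printed cells. Printed base
  values can be injected per category because published bases reflect
  unrounded source durations that the printed means cannot reproduce.

Per-minute salary rates are conventionally reported truncated to two
decimals (1513/1600 = 0.9456 → 0.94); `report_rate` follows that
convention while the unrounded rate is carried downstream.

## Synthetic data generator

The generator emulates the structure of the study data — 44 HEWs (two
per Woreda, default 22 per setting) observed 21 consecutive days, plus a
7-Woreda-per-setting salary survey — so the pipeline is testable end to
end with no external data. Per setting it targets the published
per-category mean/SD durations and encounter-mix percentages, ~900
(urban) / ~1600 (rural) billable minutes per worker-month, and salary
midpoints averaging 1419 (urban) / 1513 (rural) birr/month. All draws
come from `numpy.random.default_rng(seed)`; identical config and seed
give identical output.

Design choices that matter:

* **Log-normal durations.** Only means and SDs of the real durations are
  published; log-normal is chosen as a right-skewed, strictly positive
  family whose tail makes the 3-SD rule non-trivial.
* **Inverse calibration through the exclusion rule.** The published
  means/SDs are *post-exclusion* statistics. Sampling a log-normal
  matched to them directly and then excluding beyond 3 SD biases the
  recovered mean low — by ~17% for the highest-CV categories. The
  generator therefore solves for raw moments `(m', s')` such that the
  log-normal truncated at `m' + 3s'` has mean/SD equal to the targets,
  using closed-form truncated-log-normal moments and a fixed-point
  iteration (converges in a few dozen iterations for all published
  targets; falls back to direct matching if it cannot).
* **Exact mix apportionment.** Category counts are apportioned from the
  mix by largest remainder rather than drawn i.i.d., so realized mixes
  sit within rounding of the targets even at modest n.
* **Volume calibration.** The expected kept minutes per drawn encounter
  is `Σ pᵢ·keepᵢ·meanᵢ`; the per-worker encounter count is set so kept
  billable minutes per 30-day month hit the target.
* **Salary survey.** Woreda midpoints are drawn around the target and
  recentred so their mean is exact; ~30% of Woredas report point values,
  the rest ranges up to 200 birr wide.
* **Filler.** Travel, recordkeeping, training-received and idle events
  are interleaved so logs resemble full workdays; they exercise the
  non-billable classification path without affecting billable statistics.

What the generator does **not** emulate: within-day activity ordering
and working-hour structure, seasonal and between-day volume variation,
worker-level heterogeneity in activity mix, correlation between
durations of the same worker, and observer measurement error. Passing
recovery tests therefore show the pipeline's arithmetic is correct under
the stated statistical structure, not that the published field estimates
themselves are accurate.

## Verification set-up

Unit and property tests (hypothesis, derandomised) cover the outlier
rule against a brute-force stdlib oracle, count conservation, multiplier
distributivity within one rounding unit, currency round-trip, scale
equivariance, and exact reproduction of all 156 published fee-schedule
cells in chained mode. End-to-end recovery tests run the full pipeline
on calibrated synthetic logs of ~10,000 encounters per setting (130
rural / 220 urban synthetic workers; ~0.5 s per setting) and require
category means within 3 standard errors, mix within 2 percentage points,
and salary-per-minute within 5% of targets. `scripts/acceptance.py`
recomputes the headline quantities from scratch and writes them as JSON.

## Known limitations

* Supplies are spread uniformly via one multiplier; supply-intensive
  services (HIV test kits) are under-priced and supply-light ones
  over-priced, a limitation inherited from the model.
* The share-derivation path for multipliers is approximate by
  construction (shares sum to 104%); it exists for sensitivity analysis,
  not reproduction.
* Zero-encounter categories yield NaN means and NaN money fields; they
  are reported, not dropped, and a fee for them requires external input.
* The campaign uplift treats campaign time as uniformly lost billable
  time; no seasonal structure is modelled.
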