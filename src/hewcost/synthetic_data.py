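"""Seeded synthetic time-motion logs and Woreda salary surveys.

The generator emulates the structure of the field data the costing
pipeline consumes, so the whole pipeline is testable end to end without
any external data:

* 44 HEWs (two per Woreda in 22 Woredas, split evenly urban/rural by
  default) observed for 21 consecutive days;
* per-category encounter durations drawn from log-normal distributions
  moment-matched to the published per-category mean/SD targets (only
  means and SDs are published; the log-normal family is a modeling
  choice — right-skewed, strictly positive, heavy enough tail to make
  the 3-SD outlier rule meaningful);
* encounter category counts apportioned exactly from the target
  encounter-mix percentages (largest-remainder method) rather than drawn
  i.i.d., so realized mixes sit within rounding of the targets even at
  modest sample sizes;
* total billable volume calibrated so each worker accumulates about 900
  (urban) / 1600 (rural) billable minutes per 30-day month;
* non-billable filler events (travel, recordkeeping, training received)
  interleaved so logs resemble full observed workdays;
* optional outlier injection beyond mean + 3 SD at a configurable rate;
* per-Woreda salary ranges whose midpoints average exactly to the
  configured target (1419 urban / 1513 rural birr/month).

Everything is driven by ``numpy.random.default_rng(seed)``: the same
config and seed give byte-identical output.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .activity_model import Setting, Taxonomy, default_taxonomy
from .fee_schedule import load_reference_table

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate_observation_log",
    "generate_salary_survey",
]

SALARY_TARGETS = {Setting.URBAN: 1419.0, Setting.RURAL: 1513.0}
BILLABLE_MIN_TARGETS = {Setting.URBAN: 900.0, Setting.RURAL: 1600.0}

NON_BILLABLE_FILLER = [
    # (label, mean_min, sd_min, events per worker-day)
    ("Travel", 25.0, 12.0, 4),
    ("Recordkeeping and recording", 15.0, 8.0, 2),
    ("Receiving training and supervision", 45.0, 20.0, 0.2),
    ("Idle or waiting time", 10.0, 6.0, 1),
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for one setting's synthetic data."""

    setting: Setting
    n_workers: int = 22  # half of the 44-HEW study per setting
    n_days: int = 21
    seed: int = 0
    start_date: dt.date = dt.date(2014, 4, 14)
    duration_targets: Mapping[str, tuple[float, float]] | None = None  # id -> (mean, sd)
    encounter_mix: Mapping[str, float] | None = None  # id -> percent share
    billable_min_month_target: float | None = None
    outlier_rate: float = 0.005
    n_woredas: int = 7
    salary_target: float | None = None
    salary_midpoint_spread: float = 120.0  # SD of Woreda midpoints, birr
    salary_range_width: float = 200.0  # max width of a reported range, birr

    def __post_init__(self):
        if self.n_workers <= 0 or self.n_days <= 0 or self.n_woredas <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")

    def resolved(self, taxonomy: Taxonomy | None = None) -> "GeneratorConfig":
        """Fill unset targets from the published study conditions."""
        taxonomy = taxonomy or default_taxonomy()
        cfg = self
        if cfg.duration_targets is None or cfg.encounter_mix is None:
            ref = load_reference_table(cfg.setting)
            durs = {r.category_id: (float(r.mean_min), float(r.sd_min)) for r in ref.itertuples()}
            mix = {r.category_id: float(r.pct_encounters) for r in ref.itertuples()}
            cfg = replace(
                cfg,
                duration_targets=cfg.duration_targets or durs,
                encounter_mix=cfg.encounter_mix or mix,
            )
        if cfg.billable_min_month_target is None:
            cfg = replace(cfg, billable_min_month_target=BILLABLE_MIN_TARGETS[cfg.setting])
        if cfg.salary_target is None:
            cfg = replace(cfg, salary_target=SALARY_TARGETS[cfg.setting])
        for cid, (m, s) in cfg.duration_targets.items():
            if m <= 0:
                raise ValueError(f"{cid}: duration mean target must be positive")
            if s < 0:
                raise ValueError(f"{cid}: duration SD target must be non-negative")
        total = sum(cfg.encounter_mix.values())
        if not 95.0 <= total <= 105.0:
            raise ValueError(f"encounter mix sums to {total:.1f}%, expected ~100%")
        return cfg


def default_config(setting: Setting | str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Published-study-condition config for a setting."""
    return GeneratorConfig(setting=Setting.coerce(setting), seed=seed, **overrides)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _kept_moments(m_raw: float, s_raw: float) -> tuple[float, float, float]:
    """(keep fraction, kept mean, kept SD) after one-pass 3-SD truncation.

    Closed-form moments of a log-normal truncated at its arithmetic
    mean + 3 SD: with a = (ln c - mu)/sigma,
    E[X | X<=c] = exp(mu + sigma^2/2) Phi(a - sigma)/Phi(a) and
    E[X^2 | X<=c] = exp(2 mu + 2 sigma^2) Phi(a - 2 sigma)/Phi(a).
    """
    if s_raw == 0:
        return 1.0, m_raw, 0.0
    mu, sigma = _lognormal_params(m_raw, s_raw)
    a = (math.log(m_raw + 3.0 * s_raw) - mu) / sigma
    p = _phi(a)
    m1 = math.exp(mu + sigma**2 / 2.0) * _phi(a - sigma) / p
    m2 = math.exp(2.0 * mu + 2.0 * sigma**2) * _phi(a - 2.0 * sigma) / p
    return p, m1, math.sqrt(max(m2 - m1 * m1, 0.0))


def _calibrate_raw_moments(
    mean_target: float, sd_target: float, *, tol: float = 1e-6, max_iter: int = 200
) -> tuple[float, float, float]:
    """Raw log-normal (mean, SD) whose post-exclusion moments hit the targets.

    The published per-category means and SDs are *post-exclusion* sample
    statistics, so drawing directly from them would leave the pipeline's
    recovered means biased low once the 3-SD rule trims the tail. This
    inverts the truncation by fixed point: scale the raw moments until the
    truncated-distribution mean and SD equal the targets. Returns
    ``(raw_mean, raw_sd, keep_fraction)``; falls back to the targets
    themselves if the iteration does not converge (extreme CV targets).
    """
    m, s = mean_target, sd_target
    for _ in range(max_iter):
        p, mk, sk = _kept_moments(m, s)
        fm = mean_target / mk
        fs = sd_target / sk if sk > 0 else 1.0
        m, s = m * fm, s * fs
        if abs(fm - 1.0) < tol and abs(fs - 1.0) < tol:
            return m, s, _kept_moments(m, s)[0]
    return mean_target, sd_target, 1.0


def _apportion(total: int, shares: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` among ``shares``."""
    quotas = total * shares / shares.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_observation_log(
    config: GeneratorConfig, taxonomy: Taxonomy | None = None
) -> pd.DataFrame:
    """Generate a synthetic observation log for one setting.

    Returns a DataFrame with the standard log columns (``worker_id,
    setting, date, activity_label, duration_min``), sorted by worker and
    date. Deterministic for a fixed config and seed.
    """
    taxonomy = taxonomy or default_taxonomy()
    cfg = config.resolved(taxonomy)
    rng = np.random.default_rng(cfg.seed)
    cat_ids = sorted(cfg.encounter_mix, key=lambda c: taxonomy[c].sort_order)
    shares = np.array([cfg.encounter_mix[c] for c in cat_ids], dtype=float)
    targets = [cfg.duration_targets[c] for c in cat_ids]
    raw = [_calibrate_raw_moments(m, s) for m, s in targets]

    # calibrate total encounter count so post-exclusion billable minutes per
    # 30-day month hit the target: each drawn encounter contributes
    # keep_fraction x target_mean kept minutes in expectation
    window_min = cfg.billable_min_month_target * cfg.n_days / 30.0
    p_norm = shares / shares.sum()
    kept_min_per_encounter = float(
        sum(p * keep * m for p, keep, (m, _) in zip(p_norm, (r[2] for r in raw), targets))
    )
    n_per_worker = max(1, round(window_min / kept_min_per_encounter))
    n_total = n_per_worker * cfg.n_workers
    counts = _apportion(n_total, shares)

    labels, durations = [], []
    for cid, n, (m_raw, s_raw, _) in zip(cat_ids, counts, raw):
        if n == 0:
            continue
        mu, sigma = _lognormal_params(m_raw, s_raw)
        d = rng.lognormal(mu, sigma, size=n)
        if cfg.outlier_rate > 0:
            hit = rng.random(n) < cfg.outlier_rate
            d[hit] = m_raw + rng.uniform(4.0, 8.0, size=int(hit.sum())) * max(
                s_raw, m_raw * 0.5
            )
        labels += [taxonomy[cid].display_name] * n
        durations.append(d)
    durations = np.concatenate(durations)
    labels = np.array(labels, dtype=object)

    # scatter encounters uniformly over worker-days
    workers = np.array(
        [f"{cfg.setting.value[0].upper()}{i + 1:03d}" for i in range(cfg.n_workers)],
        dtype=object,
    )
    slot = rng.integers(0, cfg.n_workers * cfg.n_days, size=durations.size)
    dates = np.array(
        [cfg.start_date + dt.timedelta(days=int(d)) for d in range(cfg.n_days)],
        dtype=object,
    )
    frames = [
        pd.DataFrame(
            {
                "worker_id": workers[slot // cfg.n_days],
                "setting": cfg.setting.value,
                "date": dates[slot % cfg.n_days],
                "activity_label": labels,
                "duration_min": np.round(durations, 1),
            }
        )
    ]

    # non-billable filler so logs look like full workdays
    for label, m, s, per_day in NON_BILLABLE_FILLER:
        n = rng.binomial(cfg.n_workers * cfg.n_days, min(per_day, 1.0)) if per_day < 1 else int(
            round(per_day * cfg.n_workers * cfg.n_days)
        )
        if n == 0:
            continue
        mu, sigma = _lognormal_params(m, s)
        fslot = rng.integers(0, cfg.n_workers * cfg.n_days, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "worker_id": workers[fslot // cfg.n_days],
                    "setting": cfg.setting.value,
                    "date": dates[fslot % cfg.n_days],
                    "activity_label": label,
                    "duration_min": np.round(rng.lognormal(mu, sigma, size=n), 1),
                }
            )
        )
    log = pd.concat(frames, ignore_index=True)
    log = log.sort_values(
        ["worker_id", "date", "activity_label", "duration_min"], kind="stable"
    ).reset_index(drop=True)
    return log


def generate_salary_survey(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a per-Woreda salary survey for one setting.

    Woreda midpoints are centred exactly on the configured target salary
    (noise is drawn, then recentred), and each Woreda reports either a
    point value or a low-high range around its midpoint. Deterministic
    for a fixed config and seed.
    """
    cfg = config.resolved()
    # independent stream so log and survey generation do not interact
    rng = np.random.default_rng((cfg.seed, 17))
    mids = cfg.salary_target + rng.normal(0.0, cfg.salary_midpoint_spread, cfg.n_woredas)
    mids = mids - mids.mean() + cfg.salary_target
    widths = rng.uniform(0.0, cfg.salary_range_width, cfg.n_woredas)
    widths[rng.random(cfg.n_woredas) < 0.3] = 0.0  # some Woredas report a point value
    low = np.maximum(mids - widths / 2.0, 1.0)
    high = low + widths
    return pd.DataFrame(
        {
            "woreda_id": [f"W-{cfg.setting.value}-{i + 1:02d}" for i in range(cfg.n_woredas)],
            "setting": cfg.setting.value,
            "salary_low": np.round(low, 2),
            "salary_high": np.round(high, 2),
        }
    )
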