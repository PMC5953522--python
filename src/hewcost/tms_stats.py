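"""Time-motion-study summarisation.

Turns an observation log (one row per timed activity event) into the
per-category encounter statistics that drive the fee schedule: encounter
counts, percent breakdown, mean and SD duration after outlier exclusion,
and billable minutes per worker-month.

Conventions
-----------
* An encounter is one contiguous recorded activity event; adjacent events
  of the same category are not merged.
* Outliers are durations more than 3 SD above the category mean, with the
  mean and SD computed once on the full sample (single pass, no
  re-iteration). Durations are bounded below by zero, so with the SDs seen
  in this kind of data no observation can sit 3 SD *below* a positive
  mean; the exclusion is therefore one-sided by default, with a two-sided
  switch available.
* Reported SDs are sample SDs (n-1 denominator) unless ``ddof=0`` is
  requested.
* A month is standardised to 30 days when scaling an observation window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .activity_model import ActivityCategory, Setting, Taxonomy, default_taxonomy

__all__ = [
    "EncounterStats",
    "BillableTimeSummary",
    "ObservationLogError",
    "read_observation_log",
    "exclude_outliers",
    "classify_records",
    "summarize_encounters",
    "billable_minutes_per_month",
]

LOG_COLUMNS = ["worker_id", "setting", "date", "activity_label", "duration_min"]

DAYS_PER_MONTH = 30.0


class ObservationLogError(ValueError):
    """A malformed observation log, reported with the offending line."""


@dataclass(frozen=True)
class EncounterStats:
    """Per-category encounter summary after outlier exclusion."""

    category: ActivityCategory
    n_encounters: int
    pct_of_encounters: float
    mean_min: float  # NaN when n_encounters == 0
    sd_min: float  # NaN when n_encounters < 2
    n_excluded: int

    @property
    def mean_defined(self) -> bool:
        return self.n_encounters > 0


@dataclass(frozen=True)
class BillableTimeSummary:
    """Billable minutes per worker-month for one setting."""

    setting: Setting
    billable_min_per_month: float
    n_workers: int
    n_days_observed: int


def read_observation_log(path) -> pd.DataFrame:
    """Read a delimited observation log, validating every row.

    Expected header: ``worker_id, setting, date, activity_label,
    duration_min`` (ISO-8601 dates, minutes as non-negative reals).
    Errors carry 1-based file line numbers.
    """
    df = pd.read_csv(path, dtype={"worker_id": str, "activity_label": str})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationLogError(f"{path}: missing columns {missing}")
    lines = df.index + 2  # header is line 1
    settings = df["setting"].astype(str).str.strip().str.lower()
    bad = ~settings.isin([s.value for s in Setting])
    if bad.any():
        ln = int(lines[bad][0])
        raise ObservationLogError(
            f"{path}, line {ln}: unknown setting {df['setting'][bad].iloc[0]!r}"
        )
    df["setting"] = settings
    durations = pd.to_numeric(df["duration_min"], errors="coerce")
    bad = durations.isna() | (durations < 0)
    if bad.any():
        ln = int(lines[bad][0])
        raise ObservationLogError(
            f"{path}, line {ln}: invalid duration {df['duration_min'][bad].iloc[0]!r} "
            "(must be a non-negative number of minutes)"
        )
    df["duration_min"] = durations.astype(float)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except ValueError as exc:
        raise ObservationLogError(f"{path}: unparseable date ({exc})") from None
    return df[LOG_COLUMNS]


def exclude_outliers(
    durations: Sequence[float],
    *,
    two_sided: bool = False,
    ddof: int = 1,
) -> tuple[list[float], int]:
    """Drop durations more than 3 SD from the mean of the full sample.

    The mean and SD are computed once, on all values; surviving values are
    returned in input order. With ``two_sided=False`` (default) only values
    above ``mean + 3*SD`` are removed. Applying the rule again with the
    original mean/SD removes nothing (idempotence).
    """
    vals = np.asarray(list(durations), dtype=float)
    if vals.size == 0:
        raise ValueError("exclude_outliers requires at least one duration")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    hi = mu + 3.0 * sigma
    keep = vals <= hi
    if two_sided:
        keep &= vals >= mu - 3.0 * sigma
    kept = vals[keep].tolist()
    return kept, int(vals.size - keep.sum())


def classify_records(
    records: pd.DataFrame, taxonomy: Taxonomy | None = None
) -> pd.DataFrame:
    """Attach ``category_id`` and per-setting ``billable`` columns.

    Raises :class:`~hewcost.activity_model.UnmappedLabelError` on the first
    label absent from the synonym map.
    """
    taxonomy = taxonomy or default_taxonomy()
    out = records.copy()
    cats = [taxonomy.classify(lbl) for lbl in out["activity_label"]]
    out["category_id"] = [c.id for c in cats]
    out["billable"] = [
        c.billable_in(s) for c, s in zip(cats, out["setting"])
    ]
    return out


def _setting_billable(
    records: pd.DataFrame, setting: Setting | str, taxonomy: Taxonomy
) -> pd.DataFrame:
    setting = Setting.coerce(setting)
    df = records
    if "category_id" not in df.columns or "billable" not in df.columns:
        df = classify_records(df, taxonomy)
    return df[(df["setting"] == setting.value) & df["billable"]]


def summarize_encounters(
    records: pd.DataFrame,
    setting: Setting | str,
    taxonomy: Taxonomy | None = None,
    *,
    two_sided: bool = False,
    ddof: int = 1,
) -> list[EncounterStats]:
    """Per-category encounter statistics for one setting.

    Outlier exclusion runs within each category; the percent breakdown is
    over kept billable encounters. Billable categories with no encounters
    are reported with ``n_encounters=0`` and NaN mean, never dropped.
    """
    taxonomy = taxonomy or default_taxonomy()
    setting = Setting.coerce(setting)
    billable = _setting_billable(records, setting, taxonomy)
    if billable.empty:
        raise ValueError(f"no billable encounters for setting {setting.value!r}")
    kept_by_cat: dict[str, list[float]] = {}
    excl_by_cat: dict[str, int] = {}
    for cid, grp in billable.groupby("category_id"):
        kept, n_excl = exclude_outliers(
            grp["duration_min"].tolist(), two_sided=two_sided, ddof=ddof
        )
        kept_by_cat[cid] = kept
        excl_by_cat[cid] = n_excl
    total_kept = sum(len(v) for v in kept_by_cat.values())
    stats = []
    for cat in taxonomy.billable(setting):
        kept = kept_by_cat.get(cat.id, [])
        n = len(kept)
        arr = np.asarray(kept, dtype=float)
        stats.append(
            EncounterStats(
                category=cat,
                n_encounters=n,
                pct_of_encounters=100.0 * n / total_kept,
                mean_min=float(arr.mean()) if n else float("nan"),
                sd_min=float(arr.std(ddof=ddof)) if n > ddof else float("nan"),
                n_excluded=excl_by_cat.get(cat.id, 0),
            )
        )
    return stats


def billable_minutes_per_month(
    records: pd.DataFrame,
    setting: Setting | str,
    taxonomy: Taxonomy | None = None,
    *,
    days_observed: int | None = None,
    two_sided: bool = False,
    ddof: int = 1,
) -> BillableTimeSummary:
    """Average billable minutes per worker, scaled to a 30-day month.

    Each worker's kept billable minutes over the observation window are
    scaled by ``30 / days_observed`` and averaged across the setting's
    workers. ``days_observed`` defaults to the number of distinct dates in
    the setting's log. Outlier encounters are excluded per category before
    summing, so the minutes base matches the fee-schedule statistics.
    """
    taxonomy = taxonomy or default_taxonomy()
    setting = Setting.coerce(setting)
    billable = _setting_billable(records, setting, taxonomy)
    if billable.empty:
        raise ValueError(f"no billable encounters for setting {setting.value!r}")
    if days_observed is None:
        days_observed = int(billable["date"].nunique())
    if days_observed <= 0:
        raise ValueError("days_observed must be positive")

    # flag kept encounters per category with the single-pass rule
    kept_mask = pd.Series(False, index=billable.index)
    for _, grp in billable.groupby("category_id"):
        vals = grp["duration_min"].to_numpy(dtype=float)
        mu = vals.mean()
        sigma = vals.std(ddof=ddof) if vals.size > ddof else 0.0
        keep = vals <= mu + 3.0 * sigma
        if two_sided:
            keep &= vals >= mu - 3.0 * sigma
        kept_mask.loc[grp.index] = keep
    kept = billable[kept_mask]
    per_worker = kept.groupby("worker_id")["duration_min"].sum()
    scaled = per_worker * (DAYS_PER_MONTH / days_observed)
    return BillableTimeSummary(
        setting=setting,
        billable_min_per_month=float(scaled.mean()),
        n_workers=int(per_worker.size),
        n_days_observed=days_observed,
    )
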