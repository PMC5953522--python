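"""Cost arithmetic for HEW fee schedules.

The chain is classic time-driven activity-based costing:

    salary per billable minute  r  = S / M
    uplifted rate               r_u = r * u          (campaign opportunity cost)
    base salary per encounter   b   = r_u * d̄        (d̄ = mean minutes/encounter)
    total cost per encounter        = b * (1 + m)    (m = non-salary multiplier)
    US$                             = birr / e       (e birr per US$)

where S is the average monthly salary, M the billable minutes per
worker-month, u the campaign uplift, and m the sum of non-salary cost
components expressed as fractions of salary cost (supplies 1.88,
management 0.33, overhead 0.49; totals 2.70 with supplies and 0.82
without).

Money is rounded with exact decimal arithmetic, half-up: birr to one
decimal, US$ to two. Binary floating point would turn 124.5 * 3.7 into
460.6499..., corrupting a half-up 460.7. Unrounded values propagate
through the chain; rounding happens only at report fields — except in the
rounded-cell "chained" reproduction mode (see :mod:`hewcost.fee_schedule`),
where each table cell is recomputed from the already-rounded upstream cell.

Per-minute salary rates are conventionally printed truncated to two
decimals (1513/1600 = 0.9456 prints as 0.94), so :func:`report_rate`
rounds toward zero; everything downstream uses the unrounded rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .activity_model import Setting

__all__ = [
    "SalaryRecord",
    "CostShares",
    "MultiplierSet",
    "CostParameters",
    "round_birr",
    "round_usd",
    "report_rate",
    "average_salary",
    "salary_per_minute",
    "campaign_uplift",
    "derive_multipliers",
    "base_salary_per_encounter",
    "cost_per_encounter",
    "to_usd",
    "paper_parameters",
]


def _dec(x) -> Decimal:
    # via str() so the decimal sees the number a human wrote, not its
    # binary-float expansion
    return x if isinstance(x, Decimal) else Decimal(str(x))


def round_birr(amount) -> float:
    """Half-up to 1 decimal birr."""
    return float(_dec(amount).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def round_usd(amount) -> float:
    """Half-up to 2 decimal US$."""
    return float(_dec(amount).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def report_rate(rate_birr_per_min) -> float:
    """Per-minute salary rate as printed: truncated to 2 decimals."""
    return float(_dec(rate_birr_per_min).quantize(Decimal("0.01"), rounding=ROUND_DOWN))


@dataclass(frozen=True)
class SalaryRecord:
    """One Woreda's reported HEW salary (a point value or a range)."""

    woreda_id: str
    setting: Setting
    salary_low: float
    salary_high: float

    def __post_init__(self):
        if not 0 < self.salary_low <= self.salary_high:
            raise ValueError(
                f"woreda {self.woreda_id}: need 0 < low <= high, "
                f"got ({self.salary_low}, {self.salary_high})"
            )

    @property
    def midpoint(self) -> float:
        return (self.salary_low + self.salary_high) / 2.0


@dataclass(frozen=True)
class CostShares:
    """National program cost shares (fractions of total program cost)."""

    p_salary: float
    p_supplies: float
    p_management: float
    p_overhead: float

    def __post_init__(self):
        for name, p in vars(self).items():
            if not 0 < p < 1:
                raise ValueError(f"{name}={p} must be in (0, 1)")
        total = self.p_salary + self.p_supplies + self.p_management + self.p_overhead
        if not 0.95 <= total <= 1.10:
            raise ValueError(f"cost shares sum to {total:.3f}, outside [0.95, 1.10]")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"cost shares sum to {total:.2f}, not 1.00; multipliers derived "
                "from them are approximate",
                stacklevel=3,
            )


@dataclass(frozen=True)
class MultiplierSet:
    """Non-salary costs as fractions of salary cost."""

    m_supplies: float
    m_management: float
    m_overhead: float

    def __post_init__(self):
        for name, m in vars(self).items():
            if m < 0:
                raise ValueError(f"{name}={m} must be >= 0")

    @property
    def m_total_with_supplies(self) -> float:
        return self.m_supplies + self.m_management + self.m_overhead

    @property
    def m_total_no_supplies(self) -> float:
        return self.m_management + self.m_overhead


#: The published Ethiopia-specific multipliers (supplies 188%, management
#: 33%, overhead 49% of salary cost). Canonical for reproduction runs: the
#: printed totals 270%/82% are exact sums of these components, whereas the
#: national cost shares they were derived from sum to 104% and would give
#: a supplies multiplier of 55/27 = 204%.
PAPER_MULTIPLIERS = MultiplierSet(1.88, 0.33, 0.49)

PAPER_COST_SHARES = dict(p_salary=0.27, p_supplies=0.55, p_management=0.09, p_overhead=0.13)


def average_salary(
    records: Iterable[SalaryRecord], setting: Setting | str
) -> float:
    """Unweighted mean over Woredas of per-Woreda salary midpoints (birr/month)."""
    setting = Setting.coerce(setting)
    mids = [r.midpoint for r in records if r.setting == setting]
    if not mids:
        raise ValueError(f"no salary records for setting {setting.value!r}")
    return sum(mids) / len(mids)


def read_salary_survey(path) -> list[SalaryRecord]:
    """Read a Woreda salary survey: ``woreda_id, setting, salary_low, salary_high``."""
    df = pd.read_csv(path, dtype={"woreda_id": str})
    return [
        SalaryRecord(
            woreda_id=row.woreda_id,
            setting=Setting.coerce(row.setting),
            salary_low=float(row.salary_low),
            salary_high=float(row.salary_high),
        )
        for row in df.itertuples()
    ]


def salary_per_minute(salary_month: float, billable_min_month: float) -> float:
    """Salary per billable minute, S/M, unrounded (use report_rate to print)."""
    if salary_month <= 0:
        raise ValueError("salary_month must be positive")
    if billable_min_month <= 0:
        raise ValueError("billable_min_month must be positive")
    return salary_month / billable_min_month


def campaign_uplift(campaign_fraction: float) -> float:
    """Uplift u = 1/(1-f) for a fraction f of the year lost to campaigns.

    A year's salary must be recovered from the (1-f) fraction of the year
    in which billable encounters can occur, so the per-minute rate scales
    by 1/(1-f).
    """
    if not 0 <= campaign_fraction < 1:
        raise ValueError("campaign_fraction must be in [0, 1)")
    return 1.0 / (1.0 - campaign_fraction)


def derive_multipliers(shares: CostShares) -> MultiplierSet:
    """Non-salary multipliers from program cost shares: m_x = p_x / p_salary."""
    if shares.p_salary <= 0:
        raise ValueError("p_salary must be positive")
    return MultiplierSet(
        m_supplies=shares.p_supplies / shares.p_salary,
        m_management=shares.p_management / shares.p_salary,
        m_overhead=shares.p_overhead / shares.p_salary,
    )


def base_salary_per_encounter(rate_uplifted: float, mean_min: float) -> float:
    """Base salary cost of one encounter: uplifted rate x mean duration, unrounded."""
    if rate_uplifted < 0 or mean_min < 0:
        raise ValueError("rate and duration must be non-negative")
    return rate_uplifted * mean_min


def cost_per_encounter(base_salary: float, m_total: float, *, rounded: bool = True) -> float:
    """Total cost per encounter: base x (1 + m_total).

    "Multiplying salary cost by 82%/270%" is additive on top of the base:
    the fee recovers the salary cost itself plus each non-salary component
    expressed as a fraction of it. Verified cell-by-cell against the
    published tables (16.6 x 1.82 = 30.2; 124.5 x 3.70 = 460.65 -> 460.7).
    """
    if base_salary < 0:
        raise ValueError("base salary cost must be non-negative")
    if m_total < 0:
        raise ValueError("multiplier must be non-negative")
    total = _dec(base_salary) * (Decimal(1) + _dec(m_total))
    return round_birr(total) if rounded else float(total)


def to_usd(amount_birr: float, exchange_rate: float, *, rounded: bool = True) -> float:
    """Convert birr to US$ at e birr per US$ (half-up to 2 decimals)."""
    if exchange_rate <= 0:
        raise ValueError("exchange rate must be positive")
    usd = _dec(amount_birr) / _dec(exchange_rate)
    return round_usd(usd) if rounded else float(usd)


@dataclass(frozen=True)
class CostParameters:
    """Complete parameter set for one setting's fee schedule."""

    setting: Setting
    salary_month: float  # S, birr/month
    billable_min_month: float  # M, minutes per worker-month
    campaign_fraction: float = 0.1742  # f, fraction of the year on campaigns
    rate_uplifted_override: float | None = None  # inject a printed r_u verbatim
    exchange_rate: float = 22.0  # e, birr per US$
    multipliers: MultiplierSet = field(default_factory=lambda: PAPER_MULTIPLIERS)

    def __post_init__(self):
        if self.salary_month <= 0 or self.billable_min_month <= 0:
            raise ValueError("salary and billable minutes must be positive")
        if self.exchange_rate <= 0:
            raise ValueError("exchange rate must be positive")
        if not 0 <= self.campaign_fraction < 1:
            raise ValueError("campaign_fraction must be in [0, 1)")

    @property
    def rate_base(self) -> float:
        """Salary per billable minute r = S/M, birr/min, unrounded."""
        return salary_per_minute(self.salary_month, self.billable_min_month)

    @property
    def uplift_factor(self) -> float:
        return campaign_uplift(self.campaign_fraction)

    @property
    def rate_uplifted(self) -> float:
        """Campaign-adjusted rate r_u, birr/min.

        Uses the override when set (reproduction runs inject the printed
        1.88 urban / 1.25 rural rates, which do not follow from any single
        uplift formula); otherwise r * 1/(1-f).
        """
        if self.rate_uplifted_override is not None:
            return self.rate_uplifted_override
        return self.rate_base * self.uplift_factor

    def snapshot(self) -> dict:
        """Flat audit record embedded in fee-schedule outputs."""
        return {
            "setting": self.setting.value,
            "salary_month_birr": self.salary_month,
            "billable_min_month": self.billable_min_month,
            "rate_base_birr_per_min": self.rate_base,
            "campaign_fraction": self.campaign_fraction,
            "rate_uplifted_birr_per_min": self.rate_uplifted,
            "rate_uplifted_overridden": self.rate_uplifted_override is not None,
            "m_supplies": self.multipliers.m_supplies,
            "m_management": self.multipliers.m_management,
            "m_overhead": self.multipliers.m_overhead,
            "m_total_with_supplies": self.multipliers.m_total_with_supplies,
            "m_total_no_supplies": self.multipliers.m_total_no_supplies,
            "exchange_rate_birr_per_usd": self.exchange_rate,
        }


#: Published study conditions per setting: average salaries from the
#: 7-Woreda survey, observed billable minutes per month, and the printed
#: campaign-adjusted per-minute rates.
PAPER_CONDITIONS = {
    Setting.URBAN: dict(salary_month=1419.0, billable_min_month=900.0, rate_uplifted=1.88),
    Setting.RURAL: dict(salary_month=1513.0, billable_min_month=1600.0, rate_uplifted=1.25),
}


def paper_parameters(
    setting: Setting | str, *, use_printed_rates: bool = True
) -> CostParameters:
    """CostParameters preloaded with the published study conditions."""
    setting = Setting.coerce(setting)
    cond = PAPER_CONDITIONS[setting]
    return CostParameters(
        setting=setting,
        salary_month=cond["salary_month"],
        billable_min_month=cond["billable_min_month"],
        rate_uplifted_override=cond["rate_uplifted"] if use_printed_rates else None,
    )


def parameters_from_data(
    setting: Setting | str,
    salary_records: Iterable[SalaryRecord],
    billable_summary,
    *,
    campaign_fraction: float = 0.1742,
    exchange_rate: float = 22.0,
    multipliers: MultiplierSet | None = None,
    rate_uplifted_override: float | None = None,
) -> CostParameters:
    """Assemble CostParameters from a salary survey and a billable-time summary."""
    setting = Setting.coerce(setting)
    return CostParameters(
        setting=setting,
        salary_month=average_salary(salary_records, setting),
        billable_min_month=billable_summary.billable_min_per_month,
        campaign_fraction=campaign_fraction,
        rate_uplifted_override=rate_uplifted_override,
        exchange_rate=exchange_rate,
        multipliers=multipliers or PAPER_MULTIPLIERS,
    )
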