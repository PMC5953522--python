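"""Fee-schedule assembly, rendering, serialisation and regression checks.

A fee schedule has one line per billable activity category in a setting
(12 urban, 14 rural), each carrying the encounter statistics and the cost
of one encounter under two cost-recovery scenarios:

* 82% non-salary rate — management + overhead only (supplies donated);
* 270% non-salary rate — supplies + management + overhead (full cost).

Two computation modes are supported:

``unrounded``
    The default analysis mode: unrounded values propagate through the
    whole chain (rate x mean -> base -> totals) and rounding happens only
    at the report fields.

``chained``
    Reproduction mode for published tables, which chain already-rounded
    cells: each cell is recomputed from the rounded upstream cell (totals
    from the rounded base birr, US$ from the rounded birr). Printed base
    values can be injected via ``base_overrides`` because published bases
    reflect unrounded source durations not recoverable from the printed
    means.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .activity_model import ActivityCategory, Setting, Taxonomy, default_taxonomy
from .cost_engine import (
    CostParameters,
    base_salary_per_encounter,
    cost_per_encounter,
    paper_parameters,
    round_birr,
    to_usd,
)
from .tms_stats import EncounterStats

__all__ = [
    "FeeLine",
    "FeeSchedule",
    "Discrepancy",
    "build_fee_schedule",
    "build_reference_schedule",
    "load_reference_table",
    "compare_to_reference",
    "render_encounter_form",
]

MONEY_COLUMNS = [
    "base_birr",
    "base_usd",
    "cost82_birr",
    "cost82_usd",
    "cost270_birr",
    "cost270_usd",
]
STAT_COLUMNS = ["pct_encounters", "mean_min", "sd_min"]


@dataclass(frozen=True)
class FeeLine:
    category: ActivityCategory
    pct_encounters: float
    mean_min: float
    sd_min: float
    base_birr: float
    base_usd: float
    cost82_birr: float
    cost82_usd: float
    cost270_birr: float
    cost270_usd: float

    def as_dict(self) -> dict:
        d = {"category_id": self.category.id, "display_name": self.category.display_name}
        for col in STAT_COLUMNS + MONEY_COLUMNS:
            d[col] = getattr(self, col)
        return d


@dataclass(frozen=True)
class FeeSchedule:
    setting: Setting
    lines: tuple[FeeLine, ...]
    parameters: CostParameters
    mode: str
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        expected = {Setting.URBAN: 12, Setting.RURAL: 14}[self.setting]
        if len(self.lines) != expected:
            raise ValueError(
                f"{self.setting.value} schedule must have {expected} lines, "
                f"got {len(self.lines)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([ln.as_dict() for ln in self.lines])

    def line(self, category_id: str) -> FeeLine:
        for ln in self.lines:
            if ln.category.id == category_id:
                return ln
        raise KeyError(category_id)

    def write_csv(self, path) -> None:
        """Write the schedule with its parameter snapshot as '#' header lines."""
        buf = io.StringIO()
        buf.write(f"# hewcost fee schedule\n# mode={self.mode}\n")
        for k, v in self.parameters.snapshot().items():
            buf.write(f"# {k}={v}\n")
        for k, v in self.provenance.items():
            buf.write(f"# provenance.{k}={v}\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def read_csv(cls, path, taxonomy: Taxonomy | None = None) -> "FeeSchedule":
        taxonomy = taxonomy or default_taxonomy()
        meta: dict[str, str] = {}
        body: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                if raw.startswith("#"):
                    stripped = raw[1:].strip()
                    if "=" in stripped:
                        k, v = stripped.split("=", 1)
                        meta[k.strip()] = v.strip()
                else:
                    body.append(raw)
        df = pd.read_csv(io.StringIO("".join(body)))
        from .cost_engine import MultiplierSet

        params = CostParameters(
            setting=Setting.coerce(meta["setting"]),
            salary_month=float(meta["salary_month_birr"]),
            billable_min_month=float(meta["billable_min_month"]),
            campaign_fraction=float(meta["campaign_fraction"]),
            rate_uplifted_override=(
                float(meta["rate_uplifted_birr_per_min"])
                if meta.get("rate_uplifted_overridden") == "True"
                else None
            ),
            exchange_rate=float(meta["exchange_rate_birr_per_usd"]),
            multipliers=MultiplierSet(
                float(meta["m_supplies"]),
                float(meta["m_management"]),
                float(meta["m_overhead"]),
            ),
        )
        lines = tuple(
            FeeLine(category=taxonomy[row.category_id], **{c: getattr(row, c) for c in STAT_COLUMNS + MONEY_COLUMNS})
            for row in df.itertuples()
        )
        prov = {k.split(".", 1)[1]: v for k, v in meta.items() if k.startswith("provenance.")}
        return cls(
            setting=params.setting,
            lines=lines,
            parameters=params,
            mode=meta.get("mode", "unrounded"),
            provenance=prov,
        )


def _money_fields(base_unrounded: float, params: CostParameters, mode: str) -> dict:
    """The six money cells from an unrounded base, per the computation mode."""
    m82 = params.multipliers.m_total_no_supplies
    m270 = params.multipliers.m_total_with_supplies
    e = params.exchange_rate
    if math.isnan(base_unrounded):
        return {c: float("nan") for c in MONEY_COLUMNS}
    if mode == "chained":
        base_b = round_birr(base_unrounded)
        c82_b = cost_per_encounter(base_b, m82)
        c270_b = cost_per_encounter(base_b, m270)
        return dict(
            base_birr=base_b,
            base_usd=to_usd(base_b, e),
            cost82_birr=c82_b,
            cost82_usd=to_usd(c82_b, e),
            cost270_birr=c270_b,
            cost270_usd=to_usd(c270_b, e),
        )
    c82 = base_unrounded * (1.0 + m82)
    c270 = base_unrounded * (1.0 + m270)
    return dict(
        base_birr=round_birr(base_unrounded),
        base_usd=to_usd(base_unrounded, e),
        cost82_birr=round_birr(c82),
        cost82_usd=to_usd(c82, e),
        cost270_birr=round_birr(c270),
        cost270_usd=to_usd(c270, e),
    )


def build_fee_schedule(
    stats: Sequence[EncounterStats],
    params: CostParameters,
    *,
    mode: str = "unrounded",
    base_overrides: Mapping[str, float] | None = None,
    taxonomy: Taxonomy | None = None,
    provenance: Mapping[str, str] | None = None,
) -> FeeSchedule:
    """Assemble a fee schedule from encounter statistics and cost parameters.

    ``stats`` must cover every billable category of the setting; a missing
    category raises with the gap listed. Lines come out in canonical
    taxonomy (published-table) order. ``base_overrides`` maps category ids
    to externally fixed base salary costs per encounter (used to inject
    printed bases in chained mode).
    """
    if mode not in ("unrounded", "chained"):
        raise ValueError(f"unknown mode {mode!r}")
    taxonomy = taxonomy or default_taxonomy()
    by_cat = {s.category.id: s for s in stats}
    billable = taxonomy.billable(params.setting)
    missing = [c.id for c in billable if c.id not in by_cat]
    if missing:
        raise ValueError(
            f"stats missing billable categories for {params.setting.value}: {missing}"
        )
    overrides = dict(base_overrides or {})
    lines = []
    for cat in billable:
        s = by_cat[cat.id]
        if cat.id in overrides:
            base = float(overrides[cat.id])
        else:
            base = base_salary_per_encounter(params.rate_uplifted, s.mean_min) if s.mean_defined else float("nan")
        lines.append(
            FeeLine(
                category=cat,
                pct_encounters=s.pct_of_encounters,
                mean_min=s.mean_min,
                sd_min=s.sd_min,
                **_money_fields(base, params, mode),
            )
        )
    return FeeSchedule(
        setting=params.setting,
        lines=tuple(lines),
        parameters=params,
        mode=mode,
        provenance=dict(provenance or {}),
    )


def load_reference_table(setting: Setting | str) -> pd.DataFrame:
    """Packaged published fee-schedule table for a setting."""
    setting = Setting.coerce(setting)
    text = (
        resources.files("hewcost.data")
        .joinpath(f"reference_{setting.value}.csv")
        .read_text(encoding="utf-8")
    )
    return pd.read_csv(io.StringIO(text))


def build_reference_schedule(
    setting: Setting | str,
    params: CostParameters | None = None,
    taxonomy: Taxonomy | None = None,
) -> FeeSchedule:
    """Rebuild a published fee schedule in rounded-cell chaining mode.

    The packaged reference table supplies the printed inputs (percent
    breakdown, mean/SD durations, base salary per encounter); every
    downstream cell (US$ bases and all four totals) is recomputed from
    them at run time.
    """
    setting = Setting.coerce(setting)
    taxonomy = taxonomy or default_taxonomy()
    params = params or paper_parameters(setting)
    ref = load_reference_table(setting)
    stats = [
        EncounterStats(
            category=taxonomy[row.category_id],
            n_encounters=0,
            pct_of_encounters=row.pct_encounters,
            mean_min=row.mean_min,
            sd_min=row.sd_min,
            n_excluded=0,
        )
        for row in ref.itertuples()
    ]
    overrides = dict(zip(ref["category_id"], ref["base_birr"]))
    return build_fee_schedule(
        stats,
        params,
        mode="chained",
        base_overrides=overrides,
        taxonomy=taxonomy,
        provenance={"inputs": f"packaged reference_{setting.value}.csv (printed cells)"},
    )


@dataclass(frozen=True)
class Discrepancy:
    category_id: str
    column: str
    got: float
    expected: float

    @property
    def abs_diff(self) -> float:
        return abs(self.got - self.expected)

    def __str__(self) -> str:
        return (
            f"{self.category_id}.{self.column}: got {self.got}, "
            f"expected {self.expected} (|diff|={self.abs_diff:.3g})"
        )


def compare_to_reference(
    schedule: FeeSchedule,
    reference: pd.DataFrame | None = None,
    *,
    tol_birr: float = 0.1,
    tol_usd: float = 0.01,
    tol_stats: float | None = None,
) -> list[Discrepancy]:
    """Cell-by-cell regression check of a schedule against a reference table.

    Money cells are compared at ±``tol_birr`` / ±``tol_usd`` (defaults suit
    printed-cell chaining mode; use ~0.5 birr for unrounded end-to-end
    runs). Percent/mean/SD columns are compared only when ``tol_stats`` is
    given. An empty list means the schedule reproduces the reference.
    """
    if reference is None:
        reference = load_reference_table(schedule.setting)
    got = schedule.to_frame().set_index("category_id")
    exp = reference.set_index("category_id")
    if set(got.index) != set(exp.index):
        raise ValueError(
            "category sets differ: schedule has "
            f"{sorted(set(got.index) - set(exp.index))} extra, reference has "
            f"{sorted(set(exp.index) - set(got.index))} extra"
        )
    out: list[Discrepancy] = []
    checks = [(c, tol_usd if c.endswith("_usd") else tol_birr) for c in MONEY_COLUMNS]
    if tol_stats is not None:
        checks += [(c, tol_stats) for c in STAT_COLUMNS]
    for cid in exp.index:
        for col, tol in checks:
            g, x = float(got.at[cid, col]), float(exp.at[cid, col])
            if not (abs(g - x) <= tol + 1e-9):
                out.append(Discrepancy(cid, col, g, x))
    return out


def render_encounter_form(schedule: FeeSchedule) -> str:
    """Render a plain-text tally sheet for front-line fee collection.

    One row per billable activity with the fee under each cost-recovery
    scenario and a blank tally/count box; deterministic layout.
    """
    if not schedule.lines:
        raise ValueError("cannot render a form for an empty schedule")
    title = f"HEW encounter form — {schedule.setting.value} fee schedule"
    header = ["Activity", "Fee (82%) birr", "Fee (270%) birr", "Tally", "Count"]
    rows = [
        [
            ln.category.display_name,
            f"{ln.cost82_birr:.1f}",
            f"{ln.cost270_birr:.1f}",
            "",
            "",
        ]
        for ln in schedule.lines
    ]
    widths = [
        max(len(header[i]), *(len(r[i]) for r in rows), 10 if i >= 3 else 0)
        for i in range(len(header))
    ]

    def fmt(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"

    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    out = [title, "=" * len(title), "", fmt(header), sep]
    out += [fmt(r) for r in rows]
    out += [
        "",
        f"Fees assume {schedule.parameters.exchange_rate:g} birr per US$; "
        "82% rate excludes supplies, 270% includes them.",
    ]
    return "\n".join(out) + "\n"
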