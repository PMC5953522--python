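"""Activity taxonomy for health extension worker (HEW) costing.

The costing unit is the fee-schedule row: 12 billable activity categories
for urban HEWs and 14 for rural HEWs (rural scope adds voluntary HIV
counseling/testing and TB services). Enabling activities — travel,
recordkeeping, receiving training or supervision, idle time — have an
identifiable cost but no identifiable service user, so they are never
billable; they enter the model only through the time they absorb.

The taxonomy and the synonym map from raw observation-log labels to
category ids are packaged data files (see ``data/data_dictionary.md``),
so a new time-motion vocabulary can be supported without code changes.
Matching is deliberately exact after case/whitespace normalisation: a
label that cannot be resolved raises :class:`UnmappedLabelError` instead
of being guessed at, because a costing pipeline must be auditable.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable

__all__ = [
    "Setting",
    "ActivityCategory",
    "Taxonomy",
    "UnmappedLabelError",
    "load_taxonomy",
    "classify_activity",
]

VALID_GROUPS = frozenset(
    {
        "hygiene_environment",
        "family_health",
        "disease_prevention",
        "first_aid",
        "ncd",
        "group_training",
        "non_billable",
    }
)


class Setting(str, Enum):
    """Service-delivery setting; urban and rural HEWs have distinct scopes."""

    URBAN = "urban"
    RURAL = "rural"

    @classmethod
    def coerce(cls, value: "Setting | str") -> "Setting":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"invalid setting {value!r}: expected 'urban' or 'rural'"
            ) from None


@dataclass(frozen=True)
class ActivityCategory:
    """One fee-schedule activity category (or a non-billable bucket)."""

    id: str
    display_name: str
    group: str
    urban_billable: bool
    rural_billable: bool
    sort_order: int

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r} for category {self.id!r}")
        if self.group == "non_billable" and (self.urban_billable or self.rural_billable):
            raise ValueError(f"non-billable category {self.id!r} has a billable flag set")

    def billable_in(self, setting: Setting | str) -> bool:
        setting = Setting.coerce(setting)
        return self.urban_billable if setting is Setting.URBAN else self.rural_billable


class UnmappedLabelError(KeyError):
    """Raised when a raw activity label has no synonym-map entry."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(
            f"unmapped activity label {label!r}: add it to the synonym map "
            "(hewcost/data/synonyms.csv) or a custom map"
        )


def _normalize(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).casefold()


class Taxonomy:
    """The activity taxonomy plus its raw-label synonym map."""

    def __init__(
        self,
        categories: Iterable[ActivityCategory],
        synonyms: dict[str, str],
    ):
        self.categories: dict[str, ActivityCategory] = {}
        for cat in categories:
            if cat.id in self.categories:
                raise ValueError(f"duplicate category id {cat.id!r}")
            self.categories[cat.id] = cat
        self._synonyms: dict[str, str] = {}
        for raw, cid in synonyms.items():
            if cid not in self.categories:
                raise ValueError(f"synonym {raw!r} maps to unknown category {cid!r}")
            self._synonyms[_normalize(raw)] = cid
        # ids and display names always resolve to themselves
        for cat in self.categories.values():
            self._synonyms.setdefault(_normalize(cat.id), cat.id)
            self._synonyms.setdefault(_normalize(cat.display_name), cat.id)

    def __getitem__(self, category_id: str) -> ActivityCategory:
        return self.categories[category_id]

    def __iter__(self):
        return iter(sorted(self.categories.values(), key=lambda c: c.sort_order))

    def billable(self, setting: Setting | str) -> list[ActivityCategory]:
        """Billable categories for a setting, in canonical fee-schedule order."""
        setting = Setting.coerce(setting)
        return [c for c in self if c.billable_in(setting)]

    def classify(self, raw_label: str) -> ActivityCategory:
        """Resolve a raw observation-log label to its category.

        Raises
        ------
        UnmappedLabelError
            If the normalised label has no synonym-map entry. Unknown
            labels are never silently dropped.
        """
        if not raw_label or not raw_label.strip():
            raise ValueError("activity label must be non-empty")
        key = _normalize(raw_label)
        if key not in self._synonyms:
            raise UnmappedLabelError(raw_label)
        return self.categories[self._synonyms[key]]

    @property
    def known_labels(self) -> frozenset[str]:
        return frozenset(self._synonyms)


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    text = resources.files("hewcost.data").joinpath(name).read_text(encoding="utf-8")
    return list(csv.DictReader(text.splitlines()))


def load_taxonomy(
    taxonomy_rows: Iterable[dict[str, str]] | None = None,
    synonym_rows: Iterable[dict[str, str]] | None = None,
) -> Taxonomy:
    """Load the packaged taxonomy and synonym map (or caller-supplied rows).

    Rows mirror the packaged CSV columns: ``id, display_name, group,
    urban_billable, rural_billable, sort_order`` and
    ``raw_label, category_id``.
    """
    if taxonomy_rows is None:
        taxonomy_rows = _read_packaged_csv("taxonomy.csv")
    if synonym_rows is None:
        synonym_rows = _read_packaged_csv("synonyms.csv")
    cats = [
        ActivityCategory(
            id=row["id"],
            display_name=row["display_name"],
            group=row["group"],
            urban_billable=bool(int(row["urban_billable"])),
            rural_billable=bool(int(row["rural_billable"])),
            sort_order=int(row["sort_order"]),
        )
        for row in taxonomy_rows
    ]
    synonyms = {row["raw_label"]: row["category_id"] for row in synonym_rows}
    return Taxonomy(cats, synonyms)


_DEFAULT: Taxonomy | None = None


def default_taxonomy() -> Taxonomy:
    """The packaged taxonomy, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_taxonomy()
    return _DEFAULT


def classify_activity(
    raw_label: str,
    setting: Setting | str,
    taxonomy: Taxonomy | None = None,
) -> tuple[ActivityCategory, bool]:
    """Classify a raw label and report whether it is billable in ``setting``.

    Returns ``(category, billable)``. A category that is billable elsewhere
    but not in this setting (e.g. TB services observed for an urban HEW) is
    returned with ``billable=False``; its minutes count as non-billable time
    for that setting.
    """
    taxonomy = taxonomy or default_taxonomy()
    setting = Setting.coerce(setting)
    cat = taxonomy.classify(raw_label)
    return cat, cat.billable_in(setting)
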