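"""Patient-facing value objects shared across the engine and calculators.

A :class:`PatientRecord` is a typed bag of clinical variables keyed by the
data dictionary plus a structured medication list.  By construction there are
no slots for identifying information (name, date of birth, address, record
number): requests travel with an opaque ``session_id`` only.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import Any, Iterable, Mapping

__all__ = [
    "Medication",
    "PatientRecord",
    "RecommendationItem",
    "RecommendationSet",
]

#: Formulations a medication entry may carry.
FORMULATIONS = ("immediate-release", "extended-release", "patch", "tablet")


@dataclass(frozen=True)
class Medication:
    """One entry of a patient's medication list.

    ``dose`` is the per-administration amount in mg (for a transdermal patch,
    the delivery rate in mcg/hr).  ``dose_24h`` is the actual total taken over
    the preceding 24 hours in the same unit; dose titration works from actual
    use, not from the prescribed ceiling.  ``tablets_per_dose`` is set for
    tablet-count regimens (laxatives) where titration is expressed in tablets.
    """

    drug: str
    drug_class: str
    dose: Decimal
    route: str = "oral"
    schedule: str = ""
    formulation: str = "tablet"
    dose_24h: Decimal = Decimal(0)
    tablets_per_dose: Decimal | None = None

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.dose < 0 or self.dose_24h < 0:
            raise ValueError("medication doses must be non-negative")


@dataclass(frozen=True)
class PatientRecord:
    """Typed map of clinical variables for one visit.

    ``values`` holds raw (patient-reported or charted) variables only;
    derived quantities such as creatinine clearance are computed on demand
    during evaluation and never stored here.

    ``medications=None`` means the medication history was not reviewed (so
    the completeness gate treats it as missing); an empty tuple means it was
    reviewed and the patient takes nothing.
    """

    values: Mapping[str, Any] = field(default_factory=dict)
    medications: tuple[Medication, ...] | None = None
    visit_date: _dt.date | None = None
    session_id: str = ""

    def has(self, name: str) -> bool:
        return name in self.values and self.values[name] is not None

    def get(self, name: str) -> Any:
        return self.values[name]

    def without(self, *names: str) -> "PatientRecord":
        """Copy with the given raw variables removed (for gating tests)."""
        kept = {k: v for k, v in self.values.items() if k not in names}
        return replace(self, values=kept)

    def with_values(self, **updates: Any) -> "PatientRecord":
        merged = dict(self.values)
        merged.update(updates)
        return replace(self, values=merged)

    def meds_of_class(self, drug_class: str) -> tuple[Medication, ...]:
        return tuple(m for m in self.medications or () if m.drug_class == drug_class)


@dataclass(frozen=True)
class RecommendationItem:
    """A single rendered care-guidance statement.

    ``category`` is one of medication / lab / referral / self-care-toolkit.
    ``fields`` carries the structured dose parameters (drug, dose, unit,
    frequency, caps) alongside the prose so downstream diffs are field-level.
    """

    category: str
    text: str
    fields: Mapping[str, Any] = field(default_factory=dict)

    CATEGORIES = ("medication", "lab", "referral", "self-care-toolkit")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown recommendation category {self.category!r}")
        if "{" in self.text or "}" in self.text:
            raise ValueError(f"unfilled template slot in rendered text: {self.text!r}")


@dataclass(frozen=True)
class RecommendationSet:
    """Ordered recommendations produced by one algorithm traversal."""

    items: tuple[RecommendationItem, ...] = ()

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def by_category(self, category: str) -> tuple[RecommendationItem, ...]:
        return tuple(i for i in self.items if i.category == category)

    def texts(self) -> tuple[str, ...]:
        return tuple(i.text for i in self.items)


def as_decimal(value: Any) -> Decimal:
    """Convert numeric input to exact decimal via its string form.

    Going through ``str`` keeps 0.9 as 9/10 rather than the nearest binary
    float, so rendered doses never show binary round-off.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):
        return Decimal(str(value))
    return Decimal(value)


def med_list(entries: Iterable[Mapping[str, Any]]) -> tuple[Medication, ...]:
    """Build a medication tuple from plain dicts (fixture/XML convenience)."""
    out = []
    for e in entries:
        kwargs = dict(e)
        for key in ("dose", "dose_24h", "tablets_per_dose"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = as_decimal(kwargs[key])
        out.append(Medication(**kwargs))
    return tuple(out)
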