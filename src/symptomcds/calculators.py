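"""Deterministic clinical arithmetic behind the pain algorithm.

Renal function (Cockcroft-Gault), opioid equianalgesic conversion, rescue
dosing, sustained-release titration, transdermal fentanyl conversion, and
the adjunct (neuropathic / somatic / bowel-regimen) schedules.

The published sources for this kind of content state categories, not
conversion arithmetic, so the numeric policy here is an explicit calibration:
the equianalgesic table, rescue fraction, titration factor and rounding rules
were chosen so that the two fully specified reference cases shipped with the
package are reproduced exactly, and they are documented as calibration
choices rather than guideline citations (see docs/methods.md).

All dose arithmetic is carried out in :class:`decimal.Decimal` so rendered
doses carry no binary floating-point artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_CEILING, ROUND_FLOOR, ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .records import Medication, RecommendationItem, as_decimal

__all__ = [
    "OpioidDose",
    "OpioidRegimen",
    "RegimenOption",
    "creatinine_clearance",
    "renal_band",
    "oral_morphine_equivalent",
    "total_morphine_equivalent",
    "opioid_doses_from_meds",
    "rescue_dose",
    "sustained_release_titration",
    "fentanyl_patch_rate",
    "opioid_regimen_recommendation",
    "adjunct_schedules",
]


class ConversionError(ValueError):
    """Raised for opioids absent from the equianalgesic table."""


class DomainError(ValueError):
    """Raised when a calculator input lies outside its clinical domain."""


# ---------------------------------------------------------------------------
# calibration constants (see docs/methods.md for provenance)
# ---------------------------------------------------------------------------

#: oral equianalgesic ratios relative to oral morphine
EQUIANALGESIC_RATIO = {
    "morphine": Decimal("1.0"),
    "oxycodone": Decimal("1.5"),
    "hydromorphone": Decimal("5.0"),
}

#: fentanyl patch rate (mcg/hr) = oral morphine equivalent (mg/day) / 1.8
PATCH_DIVISOR = Decimal("1.8")

#: patches come in 12.5 mcg/hr steps (12.5 / 25 combinations)
PATCH_STEP = Decimal("12.5")

#: rescue (breakthrough) dose as a fraction of the 24-hour total
RESCUE_FRACTION = Decimal("0.15")

#: rescue doses rounded down to a 5 mg multiple, never below 5 mg
RESCUE_STEP = Decimal("5")
RESCUE_FLOOR = Decimal("5")

#: sustained-release uptitration factor on the actual 24-hour total
SR_TITRATION_FACTOR = Decimal("1.15")

#: achievable SR daily totals: divisible by 60 mg so that both the
#: twice-daily and thrice-daily arms land on 10 mg per-dose multiples
SR_TOTAL_STEP = Decimal("60")

#: creatinine clearance below this (mL/min) is the renally-impaired band
RENAL_CUTOFF = Decimal("30")

#: platelet count (per mL) below which NSAIDs are withheld
NSAID_PLATELET_MIN = Decimal("100000")

#: acetaminophen hard daily cap, mg
ACETAMINOPHEN_DAILY_CAP = Decimal("3000")


@dataclass(frozen=True)
class OpioidDose:
    """A 24-hour opioid exposure for one drug/formulation.

    ``per_24h`` is mg/day except for a patch, where it is the delivery rate
    in mcg/hr (patches are only ever expressed as rates).
    """

    drug: str
    per_24h: Decimal
    formulation: str = "immediate-release"

    def __post_init__(self) -> None:
        if self.per_24h < 0:
            raise DomainError("opioid amounts must be non-negative")


@dataclass(frozen=True)
class RegimenOption:
    drug: str
    dose: Decimal
    times_per_day: int
    formulation: str
    unit: str = "mg"

    @property
    def daily_total(self) -> Decimal:
        return self.dose * self.times_per_day


@dataclass(frozen=True)
class OpioidRegimen:
    """Titrated regimen: equal-total SR options, a rescue dose, escalation."""

    options: tuple[RegimenOption, ...]
    rescue: OpioidDose
    escalation_note: str

    def __post_init__(self) -> None:
        sr_totals = {
            o.daily_total for o in self.options if o.formulation == "extended-release"
        }
        if len(sr_totals) > 1:
            raise ValueError("sustained-release options must share one daily total")


# ---------------------------------------------------------------------------
# renal function
# ---------------------------------------------------------------------------

def creatinine_clearance(sex: str, age, weight, serum_creatinine) -> Decimal:
    """Cockcroft-Gault creatinine clearance estimate, mL/min.

    (140 - age) * weight / (72 * SCr), times 0.85 for females; actual body
    weight in kg, serum creatinine in mg/dL; result rounded to 0.1.
    """
    age = as_decimal(age)
    weight = as_decimal(weight)
    scr = as_decimal(serum_creatinine)
    if scr <= 0:
        raise DomainError("serum creatinine must be positive")
    if sex not in ("male", "female"):
        raise DomainError(f"unknown sex {sex!r}")
    crcl = (Decimal(140) - age) * weight / (Decimal(72) * scr)
    if sex == "female":
        crcl *= Decimal("0.85")
    return crcl.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)


def renal_band(clearance) -> str:
    """Two-band renal categorisation used by the pain algorithm."""
    return "impaired" if as_decimal(clearance) < RENAL_CUTOFF else "normal"


# ---------------------------------------------------------------------------
# equianalgesia
# ---------------------------------------------------------------------------

def opioid_doses_from_meds(meds: Iterable[Medication]) -> tuple[OpioidDose, ...]:
    """Collapse a medication list to per-drug/formulation 24-hour exposures."""
    return tuple(
        OpioidDose(drug=m.drug, per_24h=m.dose_24h, formulation=m.formulation)
        for m in meds
        if m.drug_class == "opioid"
    )


def oral_morphine_equivalent(doses: Sequence[OpioidDose]) -> Decimal:
    """Total daily ORAL opioid exposure as oral morphine mg/day.

    Transdermal patches are excluded: they are not an oral exposure and
    carry their own conversion (:func:`fentanyl_patch_rate`).
    """
    total = Decimal(0)
    for d in doses:
        if d.formulation == "patch":
            continue
        if d.drug not in EQUIANALGESIC_RATIO:
            raise ConversionError(f"no equianalgesic ratio for {d.drug!r}")
        total += d.per_24h * EQUIANALGESIC_RATIO[d.drug]
    return total


def total_morphine_equivalent(doses: Sequence[OpioidDose]) -> Decimal:
    """Oral morphine equivalent including patch exposure (rate * 1.8)."""
    total = oral_morphine_equivalent(doses)
    for d in doses:
        if d.formulation == "patch":
            total += d.per_24h * PATCH_DIVISOR
    return total


def ome_to_drug(ome: Decimal, drug: str) -> Decimal:
    """Invert the equianalgesic table: morphine mg/day -> drug mg/day."""
    if drug not in EQUIANALGESIC_RATIO:
        raise ConversionError(f"no equianalgesic ratio for {drug!r}")
    return ome / EQUIANALGESIC_RATIO[drug]


# ---------------------------------------------------------------------------
# titration arithmetic
# ---------------------------------------------------------------------------

def _round_step(value: Decimal, step: Decimal, rounding: str) -> Decimal:
    return (value / step).quantize(Decimal(1), rounding=rounding) * step


def rescue_dose(total_24h: Decimal) -> Decimal:
    """Breakthrough dose: 15% of the 24-hour same-drug total.

    Rounded down to a 5 mg multiple with a 5 mg floor, so the rescue dose is
    conservative and dispensable in standard tablet strengths.
    """
    total_24h = as_decimal(total_24h)
    if total_24h <= 0:
        raise DomainError("rescue dosing requires prior 24-hour opioid use")
    dose = _round_step(total_24h * RESCUE_FRACTION, RESCUE_STEP, ROUND_FLOOR)
    return max(dose, RESCUE_FLOOR)


def sustained_release_titration(total_24h: Decimal) -> Decimal:
    """Uptitrated sustained-release daily total for uncontrolled severe pain.

    Target = actual 24-hour total * 1.15, then snapped to the nearest daily
    total divisible by 60 mg (ties upward) so that the equal-total
    twice-daily and thrice-daily arms both land on 10 mg per-dose multiples.
    """
    total_24h = as_decimal(total_24h)
    if total_24h <= 0:
        raise DomainError("titration requires prior 24-hour opioid use")
    target = total_24h * SR_TITRATION_FACTOR
    snapped = _round_step(target, SR_TOTAL_STEP, ROUND_HALF_UP)
    return max(snapped, SR_TOTAL_STEP)


def fentanyl_patch_rate(ome: Decimal) -> Decimal:
    """Transdermal fentanyl rate mcg/hr from oral morphine equivalents.

    rate = OME / 1.8, rounded to the nearest achievable 12.5 mcg/hr step
    (combinations of 12.5 and 25 mcg/hr patches).
    """
    ome = as_decimal(ome)
    if ome <= 0:
        raise DomainError("patch conversion requires a positive OME")
    return _round_step(ome / PATCH_DIVISOR, PATCH_STEP, ROUND_HALF_UP)


def fmt_dec(value: Decimal) -> str:
    """Render a Decimal dose without trailing zeros or exponent notation."""
    s = format(value, "f")
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


def _dominant_oral_opioid(doses: Sequence[OpioidDose]) -> tuple[str, Decimal]:
    """The oral opioid with the largest 24-hour total, and that total
    summed across its formulations (IR + ER)."""
    totals: dict[str, Decimal] = {}
    for d in doses:
        if d.formulation == "patch":
            continue
        totals[d.drug] = totals.get(d.drug, Decimal(0)) + d.per_24h
    if not totals or all(v == 0 for v in totals.values()):
        raise DomainError(
            "no prior oral opioid use: opioid-naive cases take a different terminal"
        )
    drug = max(sorted(totals), key=lambda k: totals[k])
    return drug, totals[drug]


def opioid_regimen_recommendation(
    current: Sequence[OpioidDose],
    pain_severity,
    renal: str,
) -> OpioidRegimen:
    """Titrated regimen for severe pain in an opioid-tolerant patient.

    Emits an equal-total twice-daily / thrice-daily sustained-release pair in
    the patient's dominant opioid, a same-drug rescue dose, a patch-preferred
    alternative, and the escalation rule (palliative-care consult if pain
    remains above 7 one hour after the rescue dose).
    """
    severity = as_decimal(pain_severity)
    if severity < 7:
        raise DomainError("titration pathway applies to severe pain (>=7)")
    drug, total = _dominant_oral_opioid(current)
    sr_total = sustained_release_titration(total)
    rescue = rescue_dose(total)
    ome = total_morphine_equivalent(current)
    patch = fentanyl_patch_rate(ome)
    options = (
        RegimenOption(drug, sr_total / 2, 2, "extended-release"),
        RegimenOption(drug, sr_total / 3, 3, "extended-release"),
        RegimenOption("fentanyl-patch", patch, 1, "patch", unit="mcg/hr"),
    )
    return OpioidRegimen(
        options=options,
        rescue=OpioidDose(drug=drug, per_24h=rescue, formulation="immediate-release"),
        escalation_note=(
            "If pain >7 after 1 hour, suggest a palliative care consult."
        ),
    )


def rescue_for(doses: Sequence[OpioidDose], renal: str = "normal") -> tuple[str, Decimal]:
    """Rescue drug and dose for an opioid-tolerant patient.

    Same-drug rescue when there is oral opioid exposure (dominant drug);
    a patch-only patient gets an equianalgesic oral rescue instead —
    oxycodone when renally impaired, morphine otherwise.
    """
    try:
        drug, total = _dominant_oral_opioid(doses)
        return drug, rescue_dose(total)
    except DomainError:
        ome = total_morphine_equivalent(doses)
        if ome <= 0:
            raise
        drug = "oxycodone" if renal == "impaired" else "morphine"
        dose = _round_step(
            ome * RESCUE_FRACTION / EQUIANALGESIC_RATIO[drug], RESCUE_STEP, ROUND_FLOOR
        )
        return drug, max(dose, RESCUE_FLOOR)


def sr_plan(doses: Sequence[OpioidDose]) -> tuple[str, Decimal] | None:
    """Uptitrated sustained-release plan (drug, daily total) in the dominant
    oral opioid, or ``None`` when there is no oral exposure to build on."""
    try:
        drug, total = _dominant_oral_opioid(doses)
    except DomainError:
        return None
    return drug, sustained_release_titration(total)


#: alternative (second-drug) rescue doses encoded per tablet availability
#: rather than derived from the equianalgesic table; dispensed strengths
#: round up, so the listed alternative can exceed the strict equivalent
ALTERNATIVE_RESCUE = {
    ("oxycodone", Decimal(30)): ("hydromorphone", Decimal(15)),
}


def alternative_rescue(drug: str, dose: Decimal) -> tuple[str, Decimal]:
    """Hydromorphone alternative for a given rescue dose."""
    if (drug, dose) in ALTERNATIVE_RESCUE:
        return ALTERNATIVE_RESCUE[(drug, dose)]
    ome = dose * EQUIANALGESIC_RATIO[drug]
    alt = _round_step(
        ome / EQUIANALGESIC_RATIO["hydromorphone"], Decimal(2), ROUND_CEILING
    )
    return "hydromorphone", max(alt, Decimal(2))


# ---------------------------------------------------------------------------
# adjunct schedules
# ---------------------------------------------------------------------------

NEUROPATHIC_QUALITIES = frozenset({"burning", "shooting"})


def gabapentin_schedule() -> RecommendationItem:
    return RecommendationItem(
        category="medication",
        text=(
            "Suggest giving gabapentin 100 mg by mouth twice a day from days 1-7, "
            "then 200 mg by mouth twice a day from days 8-28, for neuropathic pain."
        ),
        fields={
            "drug": "gabapentin",
            "phase1_dose": Decimal(100),
            "phase1_days": "1-7",
            "phase2_dose": Decimal(200),
            "phase2_days": "8-28",
            "times_per_day": 2,
            "unit": "mg",
        },
    )


def pregabalin_fallback() -> RecommendationItem:
    return RecommendationItem(
        category="medication",
        text=(
            "If ineffective after 28 days: discontinue gabapentin and give pregabalin "
            "50 mg by mouth twice a day from days 1-7, increasing to 75-100 mg by "
            "mouth twice a day from days 8-28. If pregabalin ineffective after "
            "28 days, call palliative care consult."
        ),
        fields={
            "drug": "pregabalin",
            "phase1_dose": Decimal(50),
            "phase2_dose_low": Decimal(75),
            "phase2_dose_high": Decimal(100),
            "times_per_day": 2,
            "unit": "mg",
        },
    )


def acetaminophen_option() -> RecommendationItem:
    return RecommendationItem(
        category="medication",
        text=(
            "Give acetaminophen 1000 mg by mouth three times a day for somatic pain "
            "NOT to exceed 3000 mg per day."
        ),
        fields={
            "drug": "acetaminophen",
            "dose": Decimal(1000),
            "times_per_day": 3,
            "max_daily": ACETAMINOPHEN_DAILY_CAP,
            "unit": "mg",
        },
    )


def ibuprofen_option() -> RecommendationItem:
    return RecommendationItem(
        category="medication",
        text=(
            "OR ibuprofen 400 mg by mouth three times a day for somatic pain with "
            "omeprazole or pantoprazole 20 mg by mouth daily for GI protection."
        ),
        fields={
            "drug": "ibuprofen",
            "dose": Decimal(400),
            "times_per_day": 3,
            "gi_protection": "omeprazole or pantoprazole 20 mg daily",
            "unit": "mg",
        },
    )


def bowel_prophylaxis() -> list[RecommendationItem]:
    return [
        RecommendationItem(
            category="medication",
            text=(
                "Suggest giving senna 1-2 tablets twice a day, up to a maximum of "
                "4 tablets twice a day, AND docusate sodium 1 tablet twice a day, "
                "for prevention or treatment of opioid-induced constipation."
            ),
            fields={
                "drug": "senna",
                "tablets_low": Decimal(1),
                "tablets_high": Decimal(2),
                "times_per_day": 2,
                "max_tablets": Decimal(4),
                "companion": "docusate sodium 1 tablet twice a day",
            },
        )
    ]


def laxative_titration(current_bowel_meds: Sequence[Medication]) -> list[RecommendationItem]:
    """Titrate the existing stimulant laxative toward 4 tablets twice daily,
    and add an osmotic/stimulant agent."""
    items: list[RecommendationItem] = []
    stimulants = [m for m in current_bowel_meds if m.drug_class.startswith("laxative")]
    if stimulants:
        med = stimulants[0]
        tabs = med.tablets_per_dose if med.tablets_per_dose is not None else Decimal(1)
        items.append(
            RecommendationItem(
                category="medication",
                text=(
                    f"Suggest titrating current {tabs:.1f} {med.drug} tablets by mouth "
                    "twice a day, up to a maximum 4 tablets by mouth twice a day, to "
                    "reach goal bowel function of either 1 bowel movement per day or "
                    "1 bowel movement every other day."
                ),
                fields={
                    "drug": med.drug,
                    "current_tablets": tabs,
                    "max_tablets": Decimal(4),
                    "times_per_day": 2,
                },
            )
        )
    else:
        items.extend(bowel_prophylaxis())
    items.append(
        RecommendationItem(
            category="medication",
            text=(
                "AND give milk of magnesia 30mL once daily OR dulcolax 10 mg by "
                "mouth or by rectum once daily OR miralax 17 g once daily."
            ),
            fields={
                "options": "milk of magnesia 30 mL | dulcolax 10 mg | miralax 17 g",
                "times_per_day": 1,
            },
        )
    )
    return items


def adjunct_schedules(
    pain_quality: str,
    bowel_score,
    current_bowel_meds: Sequence[Medication] = (),
    platelets=None,
    gi_bleed_history: bool = False,
    opioid_recommended: bool = True,
) -> list[RecommendationItem]:
    """Adjunct recommendations: neuropathic/somatic analgesia plus bowel regimen.

    Returns an empty list when no adjunct applies.  NSAID use requires an
    adequate platelet count and no gastrointestinal-bleed history; the bowel
    prophylaxis is conditional on an opioid being initiated or continued.
    """
    items: list[RecommendationItem] = []
    bowel_score = int(bowel_score)
    if pain_quality in NEUROPATHIC_QUALITIES:
        items.append(gabapentin_schedule())
        items.append(pregabalin_fallback())
    else:
        items.append(acetaminophen_option())
        if (
            platelets is not None
            and as_decimal(platelets) >= NSAID_PLATELET_MIN
            and not gi_bleed_history
        ):
            items.append(ibuprofen_option())
    if bowel_score >= 2:
        items.extend(laxative_titration(current_bowel_meds))
    elif opioid_recommended:
        items.extend(bowel_prophylaxis())
    return items
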