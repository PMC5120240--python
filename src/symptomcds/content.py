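"""Executable demo algorithm content and the recommendation renderer.

Ships two algorithms wired to the clinical calculators:

* a pain algorithm fragment — severity bands, six 24-hour opioid-use
  classes, a two-band renal check, a pain-quality (neuropathic vs somatic)
  adjunct block and an opioid-induced-constipation block.  It is explicitly
  a faithful *fragment*, not a clinically complete algorithm: it exists to
  exercise the engine and the exhaustive-path testing framework, and its
  terminals are calibrated so the two shipped reference cases reproduce
  their full printed recommendation sets exactly.
* a small generic symptom algorithm (anxiety or fatigue): severity bands
  routed to self-care / medication-review / supportive-referral terminals.

Templates are plain text with ``{slot}`` markers; every slot is filled by a
named deterministic binding into the calculators, so re-rendering is
byte-identical across runs and platforms.
"""

from __future__ import annotations

from decimal import Decimal
from functools import lru_cache
from string import Formatter
from typing import Any, Mapping

from . import calculators as calc
from .algorithm_model import (
    Branch,
    CategoryPredicate,
    DecisionAlgorithm,
    DecisionNode,
    Interval,
    IntervalPredicate,
    TerminalNode,
    standard_dictionary,
)
from .records import RecommendationItem
from .templates import RecommendationTemplate, register_template

__all__ = [
    "build_pain_demo",
    "build_generic_symptom_demo",
    "render_recommendation",
    "shipped_algorithms",
    "RenderingError",
]

D = Decimal

OPIOID_CLASSES = ("none", "ir-only", "sr-only", "ir-and-sr", "patch-containing", "non-adherent")
SOMATIC = frozenset({"achy", "sharp", "other"})
NEUROPATHIC = frozenset({"burning", "shooting"})


class RenderingError(ValueError):
    """A template slot could not be resolved."""


# ---------------------------------------------------------------------------
# template bindings
# ---------------------------------------------------------------------------

def _opioid_doses(ctx) -> tuple[calc.OpioidDose, ...]:
    return calc.opioid_doses_from_meds(ctx.record.medications or ())


def _renal(ctx) -> str:
    return calc.renal_band(ctx.value("creatinine_clearance"))


def _bind_rescue(ctx) -> Mapping[str, Any]:
    drug, dose = calc.rescue_for(_opioid_doses(ctx), _renal(ctx))
    return {"drug": drug, "dose": dose, "unit": "mg", "role": "rescue"}


def _bind_sr_bid(ctx) -> Mapping[str, Any] | None:
    plan = calc.sr_plan(_opioid_doses(ctx))
    if plan is None:
        return None
    drug, total = plan
    return {
        "drug": drug, "dose": total / 2,
        "times_per_day": 2, "daily_total": total, "unit": "mg",
    }


def _bind_sr_tid(ctx) -> Mapping[str, Any] | None:
    plan = calc.sr_plan(_opioid_doses(ctx))
    if plan is None:
        return None
    drug, total = plan
    return {
        "drug": drug, "dose": total / 3,
        "times_per_day": 3, "daily_total": total, "unit": "mg",
    }


def _bind_patch(ctx) -> Mapping[str, Any] | None:
    ome = calc.total_morphine_equivalent(_opioid_doses(ctx))
    if ome <= 0:
        return None
    rate = calc.fentanyl_patch_rate(ome)
    return {"drug": "fentanyl-patch", "rate": rate, "unit": "mcg/hr"}


def _bind_patch_rescue(ctx) -> Mapping[str, Any] | None:
    drug, dose = calc.rescue_for(_opioid_doses(ctx), _renal(ctx))
    alt_drug, alt_dose = calc.alternative_rescue(drug, dose)
    return {
        "drug": drug, "dose": dose,
        "alt_drug": alt_drug, "alt_dose": alt_dose, "unit": "mg",
    }


def _bind_ibuprofen(ctx) -> Mapping[str, Any] | None:
    platelets = ctx.value("platelets")
    if calc.as_decimal(platelets) < calc.NSAID_PLATELET_MIN or ctx.value("gi_bleed_history"):
        return None  # NSAID withheld: bleeding risk
    return dict(calc.ibuprofen_option().fields)


def _bind_bowel_titrate(ctx) -> Mapping[str, Any]:
    items = calc.laxative_titration(ctx.record.meds_of_class("laxative-stimulant"))
    first = items[0]
    return {"rendered_text": first.text, **first.fields}


_STATIC = {"category", "text"}


def _item_template(item: RecommendationItem, id: str, requires=()) -> RecommendationTemplate:
    """Template whose text and fields come verbatim from a calculator item."""
    return RecommendationTemplate(
        id=id, category=item.category, text=item.text, requires=tuple(requires),
        fields=dict(item.fields),
    )


# ---------------------------------------------------------------------------
# template registry
# ---------------------------------------------------------------------------

def _register_all() -> None:
    T = RecommendationTemplate
    reg = register_template

    reg(T(
        id="no-change", category="self-care-toolkit",
        text=(
            "Pain is controlled; no change to the pain treatment plan. Continue "
            "the self-care symptom management toolkit."
        ),
    ))
    reg(T(
        id="toolkit", category="self-care-toolkit",
        text="Suggest use of the self-care symptom management toolkit.",
    ))
    reg(T(
        id="generic-note", category="self-care-toolkit",
        text="Follow the standard self-care guidance for this symptom.",
    ))
    reg(T(
        id="medication-review", category="medication",
        text="Review the current medication list for agents that may aggravate this symptom.",
    ))
    reg(T(
        id="supportive-referral", category="referral",
        text="Refer to supportive care (social work, palliative care, or psychiatry).",
    ))
    reg(T(
        id="palliative-referral", category="referral",
        text="Suggest a palliative care consult for severe, poorly controlled pain.",
    ))
    reg(T(
        id="mild-analgesic", category="medication",
        text=(
            "For mild pain, suggest acetaminophen 650 mg by mouth every 6 hours "
            "as needed, NOT to exceed 3000 mg per day."
        ),
        fields={"drug": "acetaminophen", "dose": D(650), "max_daily": D(3000), "unit": "mg"},
    ))
    reg(T(
        id="adherence-counseling", category="medication",
        text=(
            "Opioid regimen reported as not taken as prescribed. Review adherence "
            "and barriers before any dose change; do not titrate until actual "
            "use is clarified."
        ),
    ))

    # opioid-naive starting options (dose ranges are fixed content, so they
    # are plain templates rather than calculator bindings)
    def naive(id, drug, lo, hi, note=""):
        reg(T(
            id=id, category="medication",
            text=(
                f"Give {drug} {calc.fmt_dec(lo)}-{calc.fmt_dec(hi)} mg by mouth "
                f"every 4 hours as needed{note}."
            ),
            fields={"drug": drug, "dose_low": lo, "dose_high": hi, "unit": "mg",
                    "frequency": "every 4 hours as needed"},
        ))

    naive("naive-moderate-morphine", "morphine sulfate Immediate Release", D("7.5"), D(15))
    naive("naive-moderate-oxycodone", "oxycodone", D(5), D(10), note=" (OR)")
    naive("naive-moderate-hydromorphone", "hydromorphone", D(2), D(4), note=" (OR)")
    naive("naive-severe-morphine", "morphine sulfate Immediate Release", D(15), D(30))
    naive("naive-severe-oxycodone", "oxycodone", D(10), D(20), note=" (OR)")
    naive("naive-severe-hydromorphone", "hydromorphone", D(4), D(8), note=" (OR)")

    renal_inputs = ("creatinine_clearance",)
    reg(T(
        id="tolerant-rescue", category="medication",
        text=(
            "For symptom relief, give {drug} at {dose} mg by mouth. If pain >7 "
            "after 1 hour, suggest a palliative care consult. If pain is <6 after "
            "1 hour, suggest you use one of the following combinations of "
            "sustained release and rescue dose opioids. Adjust to available "
            "formulations."
        ),
        binding=_bind_rescue,
        requires=("medications",) + renal_inputs,
    ))
    reg(T(
        id="tolerant-sr-bid", category="medication",
        text=(
            "If {drug} sustained release preferred: give {drug} sustained release "
            "{dose} mg by mouth twice a day."
        ),
        binding=_bind_sr_bid, requires=("medications",),
    ))
    reg(T(
        id="tolerant-sr-tid", category="medication",
        text="OR {dose} mg by mouth three times a day.",
        binding=_bind_sr_tid, requires=("medications",),
    ))
    reg(T(
        id="tolerant-sr-rescue", category="medication",
        text="Give {drug} immediate release {dose} mg by mouth every 4 hours as needed.",
        binding=_bind_rescue, requires=("medications",) + renal_inputs,
    ))
    reg(T(
        id="tolerant-patch", category="medication",
        text="If transdermal fentanyl patch preferred: give transdermal patch {rate} mcg/hr.",
        binding=_bind_patch, requires=("medications",),
    ))
    reg(T(
        id="tolerant-patch-rescue", category="medication",
        text=(
            "Give {drug} immediate release {dose} mg by mouth every 4 hours as "
            "needed OR {alt_drug} immediate release {alt_dose} mg by mouth every "
            "4 hours as needed."
        ),
        binding=_bind_patch_rescue, requires=("medications",) + renal_inputs,
    ))
    reg(T(
        id="add-ir-opioid", category="medication",
        text=(
            "Add immediate release opioids to the patient's pain control regimen: "
            "give {drug} immediate release {dose} mg by mouth every 4 hours as needed."
        ),
        binding=_bind_rescue, requires=("medications",) + renal_inputs,
    ))
    reg(T(
        id="moderate-tolerant-review", category="medication",
        text=(
            "Continue the current opioid regimen and ensure an adequate rescue "
            "dose is available: {drug} {dose} mg by mouth every 4 hours as needed."
        ),
        binding=_bind_rescue, requires=("medications",) + renal_inputs,
    ))

    aceta = calc.acetaminophen_option()
    reg(_item_template(aceta, "somatic-acetaminophen"))
    ibu = calc.ibuprofen_option()
    reg(T(
        id="somatic-ibuprofen", category="medication", text=ibu.text,
        binding=_bind_ibuprofen, requires=("platelets", "gi_bleed_history"),
    ))
    reg(_item_template(calc.gabapentin_schedule(), "neuropathic-gabapentin"))
    reg(_item_template(calc.pregabalin_fallback(), "neuropathic-pregabalin"))
    reg(_item_template(calc.bowel_prophylaxis()[0], "bowel-prophylaxis"))
    reg(T(
        id="bowel-titrate", category="medication",
        text="{rendered_text}",
        binding=_bind_bowel_titrate, requires=("medications",),
    ))
    osmotic = calc.laxative_titration(
        [calc.Medication(drug="senna", drug_class="laxative-stimulant", dose=D("8.6"),
                         tablets_per_dose=D(1))]
    )[-1]
    reg(_item_template(osmotic, "bowel-osmotic-addon"))


_register_all()


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_recommendation(template: RecommendationTemplate, ctx) -> RecommendationItem | None:
    """Instantiate one template against an evaluation context.

    Returns ``None`` when the binding reports the recommendation does not
    apply (e.g. NSAIDs withheld for low platelets).  Raises
    :class:`RenderingError` if a slot cannot be resolved.
    """
    slots = [f[1] for f in Formatter().parse(template.text) if f[1]]
    values: dict[str, Any] = {}
    if template.binding is not None:
        bound = template.binding(ctx)
        if bound is None:
            return None
        values.update(bound)
    unresolved = [s for s in slots if s not in values]
    if unresolved:
        raise RenderingError(
            f"unresolved slot(s) {unresolved} in template {template.id!r}"
        )
    shown = {
        k: calc.fmt_dec(v) if isinstance(v, Decimal) else v for k, v in values.items()
    }
    text = template.text.format(**shown) if slots else template.text
    fields = dict(template.fields)
    fields.update((k, v) for k, v in values.items() if k != "rendered_text")
    return RecommendationItem(category=template.category, text=text, fields=fields)


# ---------------------------------------------------------------------------
# graph builders
# ---------------------------------------------------------------------------

def _iv(var: str, lo, hi, lo_closed=True, hi_closed=True) -> IntervalPredicate:
    return IntervalPredicate(var, Interval(D(lo), D(hi), lo_closed, hi_closed))


def _cats(var: str, *labels: str) -> CategoryPredicate:
    return CategoryPredicate(var, frozenset(labels))


def _terminal_templates(band: str, use_class: str, renal: str, quality: str, bowel: str) -> tuple[str, ...]:
    """Recommendation templates for one pain terminal, in display order:
    opioid therapy first, then the pain-quality adjunct, then the bowel
    regimen."""
    items: list[str] = []
    if use_class == "none":
        if band == "moderate":
            if renal == "normal":
                items.append("naive-moderate-morphine")
            items += ["naive-moderate-oxycodone", "naive-moderate-hydromorphone"]
        else:
            if renal == "normal":
                items.append("naive-severe-morphine")
            items += ["naive-severe-oxycodone", "naive-severe-hydromorphone",
                      "palliative-referral"]
    elif use_class == "non-adherent":
        items.append("adherence-counseling")
        if band == "severe":
            items.append("palliative-referral")
    elif band == "moderate":
        items.append("moderate-tolerant-review")
    else:  # severe, opioid-tolerant
        if use_class == "sr-only":
            items.append("add-ir-opioid")
        else:
            items.append("tolerant-rescue")
        items += ["tolerant-sr-bid", "tolerant-sr-tid", "tolerant-sr-rescue",
                  "tolerant-patch", "tolerant-patch-rescue"]
    if quality == "somatic":
        items += ["somatic-acetaminophen", "somatic-ibuprofen"]
    else:
        items += ["neuropathic-gabapentin", "neuropathic-pregabalin"]
    if bowel == "high":
        items += ["bowel-titrate", "bowel-osmotic-addon"]
    else:  # prophylaxis whenever an opioid is recommended or continued
        items.append("bowel-prophylaxis")
    return tuple(items)


@lru_cache(maxsize=1)
def build_pain_demo() -> DecisionAlgorithm:
    """The demo pain algorithm.

    Structure: pain severity (none / mild / moderate / severe) -> 24-hour
    opioid-use class (six groups) -> renal band (creatinine clearance,
    two groups) -> pain quality (somatic vs neuropathic) -> constipation
    score — with distinct node instances per graph position, so the renal
    check contributes one decision node per position it occupies.
    """
    dictionary = standard_dictionary()
    nodes: dict[str, DecisionNode | TerminalNode] = {}

    def add(node):
        nodes[node.id] = node
        return node.id

    for band in ("moderate", "severe"):
        for cls in OPIOID_CLASSES:
            for renal in ("normal", "impaired"):
                for quality in ("somatic", "neuropathic"):
                    stem = f"{band}-{cls}-{renal}-{quality}"
                    for bowel in ("none", "mild", "high"):
                        add(TerminalNode(
                            id=f"T-{stem}-{bowel}",
                            recommendations=_terminal_templates(band, cls, renal, quality, bowel),
                        ))
                    add(DecisionNode(
                        id=f"bowel-{stem}",
                        variable="bowel_score",
                        branches=(
                            Branch(_iv("bowel_score", 0, 0), f"T-{stem}-none"),
                            Branch(_iv("bowel_score", 1, 1), f"T-{stem}-mild"),
                            Branch(_iv("bowel_score", 2, 4), f"T-{stem}-high"),
                        ),
                    ))
                stem = f"{band}-{cls}-{renal}"
                add(DecisionNode(
                    id=f"quality-{stem}",
                    variable="pain_quality",
                    branches=(
                        Branch(_cats("pain_quality", *sorted(SOMATIC)), f"bowel-{stem}-somatic"),
                        Branch(_cats("pain_quality", *sorted(NEUROPATHIC)), f"bowel-{stem}-neuropathic"),
                    ),
                ))
            add(DecisionNode(
                id=f"renal-{band}-{cls}",
                variable="creatinine_clearance",
                branches=(
                    Branch(_iv("creatinine_clearance", 30, 3000), f"quality-{band}-{cls}-normal"),
                    Branch(_iv("creatinine_clearance", 0, 30, hi_closed=False),
                           f"quality-{band}-{cls}-impaired"),
                ),
            ))
        add(DecisionNode(
            id=f"use-{band}",
            variable="opioid_use_class",
            branches=tuple(
                Branch(_cats("opioid_use_class", cls), f"renal-{band}-{cls}")
                for cls in OPIOID_CLASSES
            ),
        ))

    add(TerminalNode(id="T-no-pain", recommendations=("no-change",)))
    add(TerminalNode(id="T-mild", recommendations=("mild-analgesic", "toolkit")))
    add(DecisionNode(
        id="severity",
        variable="pain_severity",
        branches=(
            Branch(_iv("pain_severity", 0, 0), "T-no-pain"),
            Branch(_iv("pain_severity", 1, 3), "T-mild"),
            Branch(_iv("pain_severity", 4, 6), "use-moderate"),
            Branch(_iv("pain_severity", 7, 10), "use-severe"),
        ),
    ))

    return DecisionAlgorithm(name="pain", root="severity", nodes=nodes, dictionary=dictionary)


GENERIC_SYMPTOMS = ("anxiety", "fatigue")


@lru_cache(maxsize=None)
def build_generic_symptom_demo(name: str) -> DecisionAlgorithm:
    """Small severity-banded algorithm for a non-pain symptom.

    Requires only the symptom score itself — no labs, no medication list —
    which is what multi-algorithm gating tests rely on.
    """
    if name not in GENERIC_SYMPTOMS:
        raise ValueError(f"unknown generic symptom {name!r} (choose from {GENERIC_SYMPTOMS})")
    var = f"{name}_severity"
    nodes: dict[str, DecisionNode | TerminalNode] = {
        "T-low": TerminalNode(id="T-low", recommendations=("toolkit",)),
        "T-mid": TerminalNode(id="T-mid", recommendations=("medication-review", "toolkit")),
        "T-high": TerminalNode(id="T-high", recommendations=("supportive-referral", "toolkit")),
        "severity": DecisionNode(
            id="severity",
            variable=var,
            branches=(
                Branch(_iv(var, 0, 3), "T-low"),
                Branch(_iv(var, 4, 6), "T-mid"),
                Branch(_iv(var, 7, 10), "T-high"),
            ),
        ),
    }
    return DecisionAlgorithm(name=name, root="severity", nodes=nodes, dictionary=standard_dictionary())


def shipped_algorithms() -> tuple[DecisionAlgorithm, ...]:
    return (build_pain_demo(),) + tuple(build_generic_symptom_demo(n) for n in GENERIC_SYMPTOMS)


def write_content_files(directory) -> list[str]:
    """Regenerate the shipped algorithm XML files from the builders.

    The files under ``content_files/`` are build products, never hand-edited;
    this is the only writer.
    """
    from pathlib import Path

    from .algorithm_io import save_algorithm

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for alg in shipped_algorithms():
        path = directory / f"{alg.name}.xml"
        save_algorithm(alg, path)
        written.append(str(path))
    return written
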