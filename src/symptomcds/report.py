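"""Clinician report model: banded severities, medications, recommendations,
and cross-visit trend series.

Page one of the printable report summarises the current visit — medication
list, alcohol-use history, per-symptom scores colour-banded green / yellow /
red with increasing distress, and the algorithm recommendations.  Page two
is longitudinal: a treatment timeline and a per-symptom (date, score) trend
series.  Both a plain-text and an HTML rendering are provided; each is a
pure function of the history, so output is byte-identical across runs.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping, Sequence

from .records import PatientRecord
from .rule_engine import MissingDataReport, TraversalResult

__all__ = ["SeverityBand", "severity_band", "ReportModel", "build_report", "render_report"]


#: displayed symptom label -> record variable carrying its score
SYMPTOM_VARIABLES = {
    "pain": "pain_severity",
    "anxiety": "anxiety_severity",
    "depression": "depression_severity",
    "dyspnea": "dyspnea_severity",
    "fatigue": "fatigue_severity",
    "constipation": "bowel_score",
}


@dataclass(frozen=True)
class SeverityBand:
    score: Decimal
    band: str  # green | yellow | red
    label: str  # mild/none | moderate | severe


def severity_band(symptom: str, score) -> SeverityBand:
    """Colour band for a symptom score.

    0-10 symptom scales: 0-3 green (mild/none), 4-6 yellow (moderate),
    7-10 red (severe).  The 0-4 constipation scale: 0-1 green, 2 yellow,
    3-4 red.  Bands partition each scale and are monotone in the score.
    """
    if symptom not in SYMPTOM_VARIABLES:
        raise ValueError(f"unknown symptom {symptom!r}")
    s = Decimal(str(score))
    if symptom == "constipation":
        if not 0 <= s <= 4:
            raise ValueError(f"constipation score {score!r} outside 0-4")
        if s <= 1:
            return SeverityBand(s, "green", "mild/none")
        if s == 2:
            return SeverityBand(s, "yellow", "moderate")
        return SeverityBand(s, "red", "severe")
    if not 0 <= s <= 10:
        raise ValueError(f"{symptom} score {score!r} outside 0-10")
    if s <= 3:
        return SeverityBand(s, "green", "mild/none")
    if s <= 6:
        return SeverityBand(s, "yellow", "moderate")
    return SeverityBand(s, "red", "severe")


Visit = tuple[PatientRecord, Mapping[str, "TraversalResult | MissingDataReport"]]


@dataclass(frozen=True)
class ReportModel:
    """Everything the renderers need, already banded and sorted."""

    current: PatientRecord
    current_results: Mapping[str, TraversalResult | MissingDataReport]
    bands: Mapping[str, SeverityBand]
    trends: Mapping[str, tuple[tuple[str, Decimal], ...]]  # symptom -> ((date, score), ...)
    timeline: tuple[tuple[str, str], ...]  # (date, medication summary)


def _med_summary(record: PatientRecord) -> str:
    meds = record.medications
    if meds is None:
        return "medication history not reviewed"
    if not meds:
        return "none (opioid-naïve)" if not record.meds_of_class("opioid") else "none"
    return "; ".join(
        f"{m.drug} {m.dose} mg {m.schedule}".strip() for m in meds
    )


def build_report(history: Sequence[Visit]) -> ReportModel:
    """Assemble the report model from date-ordered visits (most recent last)."""
    if not history:
        raise ValueError("report requires at least one visit")
    dates = [rec.visit_date for rec, _ in history]
    if any(d is None for d in dates):
        raise ValueError("every visit needs a visit_date")
    if dates != sorted(dates):
        raise ValueError("visits must be date-ordered")

    current, current_results = history[-1]
    bands = {
        symptom: severity_band(symptom, current.get(var))
        for symptom, var in SYMPTOM_VARIABLES.items()
        if current.has(var)
    }
    trends: dict[str, tuple[tuple[str, Decimal], ...]] = {}
    for symptom, var in SYMPTOM_VARIABLES.items():
        series = tuple(
            (rec.visit_date.isoformat(), Decimal(str(rec.get(var))))
            for rec, _ in history
            if rec.has(var)
        )
        if series:
            trends[symptom] = series
    timeline = tuple((rec.visit_date.isoformat(), _med_summary(rec)) for rec, _ in history)
    return ReportModel(
        current=current,
        current_results=current_results,
        bands=bands,
        trends=trends,
        timeline=timeline,
    )


def _text_lines(model: ReportModel) -> list[str]:
    lines: list[str] = []
    lines.append("SYMPTOM MANAGEMENT REPORT")
    lines.append(f"session: {model.current.session_id or '-'}")
    lines.append(f"visit date: {model.current.visit_date.isoformat()}")
    lines.append("")
    lines.append("== Current data ==")
    lines.append(f"medications: {_med_summary(model.current)}")
    if model.current.has("alcohol_use"):
        lines.append(f"alcohol use: {'yes' if model.current.get('alcohol_use') else 'no'}")
    lines.append("")
    lines.append("== Symptom distress ==")
    for symptom in sorted(model.bands):
        b = model.bands[symptom]
        lines.append(f"  {symptom:<12} {b.score}  [{b.band.upper()}] {b.label}")
    lines.append("")
    lines.append("== Recommendations ==")
    for name, result in model.current_results.items():
        lines.append(f"-- {name} --")
        if isinstance(result, MissingDataReport):
            lines.append(f"  {result.message}")
        else:
            for item in result.recommendations:
                lines.append(f"  [{item.category}] {item.text}")
    lines.append("")
    lines.append("== Treatment timeline ==")
    for date, meds in model.timeline:
        lines.append(f"  {date}: {meds}")
    lines.append("")
    lines.append("== Symptom trends ==")
    for symptom in sorted(model.trends):
        series = " ".join(f"{d}:{s}" for d, s in model.trends[symptom])
        lines.append(f"  {symptom:<12} {series}")
    return lines


def render_report(history: Sequence[Visit], fmt: str = "text") -> str:
    """Render the two-page report as UTF-8 plain text or HTML."""
    model = build_report(history)
    if fmt == "text":
        return "\n".join(_text_lines(model)) + "\n"
    if fmt != "html":
        raise ValueError(f"unknown report format {fmt!r}")

    e = _html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>Symptom management report</title>",
        "<style>.green{background:#c8e6c9}.yellow{background:#fff9c4}"
        ".red{background:#ffcdd2}td,th{padding:2px 8px}</style></head><body>",
        "<h1>Symptom management report</h1>",
        f"<p>session: {e(model.current.session_id or '-')} | "
        f"visit: {model.current.visit_date.isoformat()}</p>",
        f"<h2>Current data</h2><p>medications: {e(_med_summary(model.current))}</p>",
        "<h2>Symptom distress</h2><table>",
        "<tr><th>symptom</th><th>score</th><th>band</th></tr>",
    ]
    for symptom in sorted(model.bands):
        b = model.bands[symptom]
        parts.append(
            f"<tr class='{b.band}'><td>{e(symptom)}</td><td>{b.score}</td>"
            f"<td>{e(b.label)}</td></tr>"
        )
    parts.append("</table><h2>Recommendations</h2>")
    for name, result in model.current_results.items():
        parts.append(f"<h3>{e(name)}</h3><ul>")
        if isinstance(result, MissingDataReport):
            parts.append(f"<li><em>{e(result.message)}</em></li>")
        else:
            for item in result.recommendations:
                parts.append(f"<li><b>[{e(item.category)}]</b> {e(item.text)}</li>")
        parts.append("</ul>")
    parts.append("<h2>Treatment timeline</h2><ul>")
    for date, meds in model.timeline:
        parts.append(f"<li>{date}: {e(meds)}</li>")
    parts.append("</ul><h2>Symptom trends</h2><table>")
    for symptom in sorted(model.trends):
        cells = "".join(f"<td>{d} → {s}</td>" for d, s in model.trends[symptom])
        parts.append(f"<tr><th>{e(symptom)}</th>{cells}</tr>")
    parts.append("</table></body></html>")
    return "\n".join(parts) + "\n"
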