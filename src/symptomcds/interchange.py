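"""XML service boundary: request/response documents keyed by session id.

Requests carry symptom scores, demographics, labs and the medication list
under an opaque session identifier — the schema has no slots for names,
birth dates, addresses or record numbers, and documents that smuggle such
elements in are rejected outright.  Responses echo the session id and carry
exactly one result per requested algorithm: either the rendered
recommendations or an insufficient-data message listing what was missing.

Transport is out of scope: :func:`serve_once` is the single in-process
service function over which any HTTP layer would be a thin adapter.
"""

from __future__ import annotations

import datetime as _dt
from decimal import Decimal
from importlib import resources
from typing import Mapping, Sequence

from lxml import etree

from .algorithm_model import DataDictionary, DecisionAlgorithm, standard_dictionary
from .records import Medication, PatientRecord
from .rule_engine import MissingDataReport, TraversalResult, evaluate_all

__all__ = [
    "parse_request",
    "render_request",
    "render_response",
    "serve_once",
    "PrivacyError",
    "SchemaError",
]


class SchemaError(ValueError):
    """Request document violates the shipped schema."""


class PrivacyError(ValueError):
    """Request document carries an identifying element."""


#: element/attribute names that would identify a patient; any appearance
#: anywhere in a request is a hard rejection
PHI_DENY_LIST = frozenset(
    {
        "name", "patient_name", "first_name", "last_name", "full_name",
        "dob", "date_of_birth", "birthdate", "birth_date",
        "address", "street", "city", "zip", "zipcode", "postal_code",
        "mrn", "medical_record_number", "record_number",
        "ssn", "social_security_number", "phone", "telephone", "email",
    }
)


def _schema() -> etree.XMLSchema:
    with resources.files("symptomcds.schemas").joinpath("request.xsd").open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def _normalise(token: str) -> str:
    return token.strip().lower().replace("-", "_")


def _phi_scan(root: etree._Element) -> None:
    for el in root.iter():
        if isinstance(el.tag, str) and _normalise(el.tag) in PHI_DENY_LIST:
            raise PrivacyError(
                f"identifying element <{el.tag}> is not accepted: requests must "
                "carry only nonidentifying patient information"
            )
        name_attr = el.get("name")
        if el.tag == "value" and name_attr and _normalise(name_attr) in PHI_DENY_LIST:
            raise PrivacyError(
                f"identifying value name {name_attr!r} is not accepted"
            )


def _typed(value_text: str, name: str, dictionary: DataDictionary):
    if name not in dictionary:
        raise SchemaError(f"unknown variable {name!r} in request")
    spec = dictionary[name]
    if spec.kind == "numeric":
        return Decimal(value_text)
    if spec.kind == "boolean":
        return value_text.strip().lower() == "true"
    return value_text


def parse_request(
    document: bytes, dictionary: DataDictionary | None = None
) -> tuple[str, PatientRecord, tuple[str, ...]]:
    """Parse, privacy-check and schema-validate a request document.

    Returns (session id, patient record, requested algorithm names).
    Values are type-checked against the data dictionary; out-of-domain
    values are rejected here rather than surfacing mid-traversal.
    """
    dictionary = dictionary or standard_dictionary()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as e:
        raise SchemaError(f"not well-formed XML: {e}") from e
    _phi_scan(root)
    schema = _schema()
    if not schema.validate(root):
        err = schema.error_log.last_error
        raise SchemaError(f"schema violation at line {err.line}: {err.message}")

    session = root.findtext("session")
    if not session or not session.strip():
        raise SchemaError("element 'session' must carry a non-empty token")

    patient_el = root.find("patient")
    values = {}
    for v in patient_el.findall("value"):
        name = v.get("name")
        value = _typed(v.text or "", name, dictionary)
        spec = dictionary[name]
        if spec.kind != "medication-list" and not spec.in_domain(value):
            raise SchemaError(f"value {v.text!r} of {name!r} outside declared domain")
        values[name] = value

    meds_el = patient_el.find("medications")
    medications = None
    if meds_el is not None:
        medications = tuple(
            Medication(
                drug=m.get("drug"),
                drug_class=m.get("class"),
                dose=Decimal(m.get("dose")),
                route=m.get("route", "oral"),
                schedule=m.get("schedule", ""),
                formulation=m.get("formulation", "tablet"),
                dose_24h=Decimal(m.get("dose-24h", "0")),
                tablets_per_dose=(
                    Decimal(m.get("tablets-per-dose"))
                    if m.get("tablets-per-dose") is not None
                    else None
                ),
            )
            for m in meds_el.findall("medication")
        )

    visit_date = None
    if patient_el.get("visit-date"):
        visit_date = _dt.date.fromisoformat(patient_el.get("visit-date"))

    record = PatientRecord(
        values=values, medications=medications, visit_date=visit_date, session_id=session
    )
    names = tuple(a.get("name") for a in root.find("algorithms").findall("algorithm"))
    return session, record, names


def render_request(
    session_id: str,
    record: PatientRecord,
    algorithm_names: Sequence[str],
) -> bytes:
    """Serialize a record into the request dialect (deterministic)."""
    root = etree.Element("request")
    etree.SubElement(root, "session").text = session_id
    patient = etree.SubElement(root, "patient")
    if record.visit_date is not None:
        patient.set("visit-date", record.visit_date.isoformat())
    for name in sorted(record.values):
        v = record.values[name]
        el = etree.SubElement(patient, "value", name=name)
        el.text = str(v).lower() if isinstance(v, bool) else str(v)
    if record.medications is not None:
        meds = etree.SubElement(patient, "medications")
        for m in record.medications:
            attrs = {
                "drug": m.drug,
                "class": m.drug_class,
                "dose": str(m.dose),
                "route": m.route,
                "schedule": m.schedule,
                "formulation": m.formulation,
                "dose-24h": str(m.dose_24h),
            }
            if m.tablets_per_dose is not None:
                attrs["tablets-per-dose"] = str(m.tablets_per_dose)
            etree.SubElement(meds, "medication", **attrs)
    algs = etree.SubElement(root, "algorithms")
    for n in algorithm_names:
        etree.SubElement(algs, "algorithm", name=n)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def render_response(
    session_id: str,
    results: Mapping[str, TraversalResult | MissingDataReport],
) -> bytes:
    """Serialize per-algorithm results; the session id is echoed verbatim.

    Insufficient-data results carry the missing-variable list; successful
    ones carry category-tagged recommendations with structured dose fields.
    """
    root = etree.Element("response", session=session_id)
    for name, result in results.items():
        if isinstance(result, MissingDataReport):
            r_el = etree.SubElement(root, "result", algorithm=name, status="insufficient-data")
            etree.SubElement(r_el, "message").text = result.message
            missing = etree.SubElement(r_el, "missing")
            for var in result.missing:
                etree.SubElement(missing, "variable").text = var
        elif isinstance(result, TraversalResult):
            r_el = etree.SubElement(root, "result", algorithm=name, status="ok",
                                    terminal=result.terminal)
            for item in result.recommendations:
                i_el = etree.SubElement(r_el, "recommendation", category=item.category)
                etree.SubElement(i_el, "text").text = item.text
                for k in sorted(item.fields):
                    etree.SubElement(i_el, "field", name=k).text = str(item.fields[k])
        else:
            raise ValueError(f"unknown result type for algorithm {name!r}")
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def serve_once(document: bytes, algorithms: Sequence[DecisionAlgorithm]) -> bytes:
    """One request-response cycle, in process.

    Unknown algorithm names in the request fail loudly rather than being
    silently dropped.
    """
    session, record, names = parse_request(document)
    by_name = {a.name: a for a in algorithms}
    unknown = [n for n in names if n not in by_name]
    if unknown:
        raise SchemaError(f"unknown algorithm(s) requested: {unknown}")
    results = evaluate_all(record, [by_name[n] for n in names])
    return render_response(session, results)
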