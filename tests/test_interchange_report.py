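"""Service boundary and clinician report."""

from __future__ import annotations

import datetime as dt
from decimal import Decimal

import pytest
from lxml import etree

from symptomcds.content import shipped_algorithms
from symptomcds.interchange import (
    PrivacyError,
    SchemaError,
    parse_request,
    render_request,
    render_response,
    serve_once,
)
from symptomcds.report import build_report, render_report, severity_band
from symptomcds.rule_engine import evaluate_all
from symptomcds.synthetic import CohortSpec, generate_patient_cohort

D = Decimal

ALL_NAMES = ("pain", "anxiety", "fatigue")


def _full_record(worked_cases):
    case1, _, _ = worked_cases
    return case1.with_values(
        anxiety_severity=D(2), fatigue_severity=D(5),
        depression_severity=D(1), dyspnea_severity=D(0),
    )


class TestRequests:
    def test_round_trip_preserves_synthetic_records(self):
        for record in generate_patient_cohort(CohortSpec(n=20, seed=7)):
            doc = render_request(record.session_id, record, ALL_NAMES)
            session, parsed, names = parse_request(doc)
            assert session == record.session_id
            assert names == ALL_NAMES
            assert parsed.values == record.values
            assert parsed.medications == record.medications

    @pytest.mark.parametrize(
        "phi_tag",
        ["patient_name", "date_of_birth", "address", "mrn", "ssn", "last-name"],
    )
    def test_identifier_elements_always_rejected(self, phi_tag, worked_cases):
        doc = render_request("S-1", _full_record(worked_cases), ALL_NAMES)
        poisoned = doc.replace(
            b"<session>", f"<{phi_tag}>x</{phi_tag}><session>".encode()
        )
        with pytest.raises(PrivacyError):
            parse_request(poisoned)

    def test_identifier_value_name_rejected(self, worked_cases):
        doc = render_request("S-1", _full_record(worked_cases), ALL_NAMES)
        poisoned = doc.replace(b'<value name="age">', b'<value name="date_of_birth">')
        with pytest.raises(PrivacyError):
            parse_request(poisoned)

    def test_missing_session_is_a_schema_error(self, worked_cases):
        doc = render_request("S-1", _full_record(worked_cases), ALL_NAMES)
        root = etree.fromstring(doc)
        root.remove(root.find("session"))
        with pytest.raises(SchemaError):
            parse_request(etree.tostring(root))

    def test_out_of_domain_value_rejected_at_parse(self, worked_cases):
        doc = render_request("S-1", _full_record(worked_cases), ALL_NAMES)
        poisoned = doc.replace(
            b'<value name="pain_severity">6</value>',
            b'<value name="pain_severity">14</value>',
        )
        with pytest.raises(SchemaError, match="pain_severity"):
            parse_request(poisoned)

    def test_every_dictionary_variable_expressible(self, worked_cases):
        """Schema completeness: each raw dictionary variable round-trips as
        exactly one value element (medication list has its own block)."""
        record = _full_record(worked_cases)
        doc = render_request("S-1", record, ALL_NAMES)
        root = etree.fromstring(doc)
        names = [v.get("name") for v in root.find("patient").findall("value")]
        assert sorted(names) == sorted(record.values)
        assert len(names) == len(set(names))


class TestResponses:
    def test_session_echo_and_one_result_per_algorithm(self, worked_cases):
        record = _full_record(worked_cases)
        algs = shipped_algorithms()
        doc = render_request("SESSION-XYZ", record, ALL_NAMES)
        resp = etree.fromstring(serve_once(doc, algs))
        assert resp.get("session") == "SESSION-XYZ"
        results = resp.findall("result")
        assert [r.get("algorithm") for r in results] == list(ALL_NAMES)
        assert all(r.get("status") == "ok" for r in results)

    def test_insufficient_data_message_lists_variables(self, worked_cases):
        record = _full_record(worked_cases).without("serum_creatinine")
        algs = shipped_algorithms()
        doc = render_request("S-2", record, ALL_NAMES)
        resp = etree.fromstring(serve_once(doc, algs))
        pain = resp.find("result[@algorithm='pain']")
        assert pain.get("status") == "insufficient-data"
        assert "insufficient" in pain.findtext("message")
        assert [v.text for v in pain.find("missing")] == ["serum_creatinine"]
        assert resp.find("result[@algorithm='fatigue']").get("status") == "ok"

    def test_rendering_is_deterministic(self, worked_cases):
        record = _full_record(worked_cases)
        algs = shipped_algorithms()
        doc = render_request("S-3", record, ALL_NAMES)
        assert serve_once(doc, algs) == serve_once(doc, algs)

    def test_unknown_algorithm_key_rejected(self):
        with pytest.raises(ValueError):
            render_response("S", {"pain": object()})


class TestSeverityBands:
    @pytest.mark.parametrize(
        "symptom, score, band, label",
        [
            ("pain", 6, "yellow", "moderate"),
            ("pain", 8, "red", "severe"),
            ("pain", 0, "green", "mild/none"),
            ("constipation", 1, "green", "mild/none"),
            ("constipation", 2, "yellow", "moderate"),
            ("constipation", 4, "red", "severe"),
        ],
    )
    def test_reference_bands(self, symptom, score, band, label):
        entry = severity_band(symptom, score)
        assert (entry.band, entry.label) == (band, label)

    def test_bands_partition_and_are_monotone(self):
        order = {"green": 0, "yellow": 1, "red": 2}
        for symptom, top in [("pain", 10), ("fatigue", 10), ("constipation", 4)]:
            bands = [order[severity_band(symptom, s).band] for s in range(top + 1)]
            assert bands == sorted(bands)
            assert set(bands) == {0, 1, 2}

    def test_out_of_domain_score_rejected(self):
        with pytest.raises(ValueError):
            severity_band("pain", 11)
        with pytest.raises(ValueError):
            severity_band("constipation", 5)


class TestReport:
    def _visits(self, worked_cases, n=1):
        algs = shipped_algorithms()
        visits = []
        for i in range(n):
            record = _full_record(worked_cases)
            record = type(record)(
                values={**record.values, "pain_severity": D(min(6 + i, 10))},
                medications=record.medications,
                visit_date=dt.date(2015, 3, 2) + dt.timedelta(days=14 * i),
                session_id=f"S-{i}",
            )
            visits.append((record, evaluate_all(record, algs)))
        return visits

    def test_single_visit_lists_meds_and_recommendations(self, worked_cases):
        text = render_report(self._visits(worked_cases), fmt="text")
        assert "none (opioid-naïve)" in text
        assert "[medication]" in text and "[self-care-toolkit]" in text
        assert "morphine sulfate Immediate Release 7.5-15 mg" in text

    def test_three_visits_build_ascending_trends(self, worked_cases):
        model = build_report(self._visits(worked_cases, n=3))
        for symptom, series in model.trends.items():
            assert len(series) == 3
            dates = [d for d, _ in series]
            assert dates == sorted(dates)

    def test_displayed_bands_match_severity_band(self, worked_cases):
        model = build_report(self._visits(worked_cases))
        for symptom, entry in model.bands.items():
            assert entry == severity_band(symptom, entry.score)

    def test_html_and_text_are_deterministic(self, worked_cases):
        visits = self._visits(worked_cases, n=2)
        assert render_report(visits, fmt="text") == render_report(visits, fmt="text")
        html = render_report(visits, fmt="html")
        assert html == render_report(visits, fmt="html")
        assert "class='yellow'" in html or "class='red'" in html

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            build_report([])

    def test_unordered_visits_rejected(self, worked_cases):
        v1, v2 = self._visits(worked_cases, n=2)
        with pytest.raises(ValueError):
            build_report([v2, v1])
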