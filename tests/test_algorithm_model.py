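"""Structural model: validation findings, complexity metrics, serialization."""

from __future__ import annotations

from decimal import Decimal

import pytest

from symptomcds.algorithm_io import ParseError, algorithm_from_xml, algorithm_to_xml
from symptomcds.algorithm_model import (
    Branch,
    CategoryPredicate,
    DecisionAlgorithm,
    DecisionNode,
    Interval,
    IntervalPredicate,
    InvalidAlgorithmError,
    TerminalNode,
    count_decision_nodes,
    count_pathways,
    required_variables,
    standard_dictionary,
    validate_algorithm,
)
from symptomcds.synthetic import build_fully_crossed

from oracle import brute_force_paths

D = Decimal


def _iv(var, lo, hi):
    return IntervalPredicate(var, Interval(D(lo), D(hi)))


def _alg(nodes, root="root", name="test"):
    return DecisionAlgorithm(name=name, root=root, nodes=nodes, dictionary=standard_dictionary())


def single_terminal():
    return _alg({"root": TerminalNode("root", ("generic-note",))})


def binary_two_levels():
    from symptomcds.algorithm_model import BooleanPredicate

    nodes = {
        "root": DecisionNode(
            "root", "pain_severity",
            (Branch(_iv("pain_severity", 0, 5), "l"), Branch(_iv("pain_severity", 6, 10), "r")),
        ),
    }
    for side in ("l", "r"):
        nodes[side] = DecisionNode(
            side, "gi_bleed_history",
            (
                Branch(BooleanPredicate("gi_bleed_history", True), f"{side}0"),
                Branch(BooleanPredicate("gi_bleed_history", False), f"{side}1"),
            ),
        )
        for leaf in (f"{side}0", f"{side}1"):
            nodes[leaf] = TerminalNode(leaf, ("generic-note",))
    return _alg(nodes)


class TestValidation:
    def test_shipped_demo_validates_clean(self, pain_demo):
        report = validate_algorithm(pain_demo)
        assert report.ok and report.findings == ()

    def test_validation_is_idempotent(self, pain_demo):
        assert validate_algorithm(pain_demo) == validate_algorithm(pain_demo)

    def test_non_exhaustive_branches_flagged(self):
        # [1,6] and [7,10] leave severity 0 uncovered on the 0-10 scale
        alg = _alg({
            "root": DecisionNode(
                "root", "pain_severity",
                (Branch(_iv("pain_severity", 1, 6), "a"), Branch(_iv("pain_severity", 7, 10), "b")),
            ),
            "a": TerminalNode("a", ("generic-note",)),
            "b": TerminalNode("b", ("generic-note",)),
        })
        report = validate_algorithm(alg)
        assert not report.ok
        assert any("non-exhaustive" in f.message and f.node_id == "root" for f in report.errors())

    def test_overlapping_branches_flagged(self):
        # both branches claim the same category
        alg = _alg({
            "root": DecisionNode(
                "root", "pain_quality",
                (
                    Branch(CategoryPredicate("pain_quality", frozenset({"achy", "sharp", "other", "burning"})), "a"),
                    Branch(CategoryPredicate("pain_quality", frozenset({"burning", "shooting"})), "b"),
                ),
            ),
            "a": TerminalNode("a", ("generic-note",)),
            "b": TerminalNode("b", ("generic-note",)),
        })
        report = validate_algorithm(alg)
        assert any("overlapping" in f.message for f in report.errors())

    def test_dangling_successor_and_empty_terminal(self):
        alg = _alg({
            "root": DecisionNode(
                "root", "pain_severity",
                (Branch(_iv("pain_severity", 0, 5), "gone"), Branch(_iv("pain_severity", 6, 10), "t")),
            ),
            "t": TerminalNode("t", ()),
        })
        msgs = [f.message for f in validate_algorithm(alg).errors()]
        assert any("dangling" in m for m in msgs)
        assert any("no recommendation" in m for m in msgs)

    def test_cycle_detected(self):
        alg = _alg({
            "root": DecisionNode(
                "root", "pain_severity",
                (Branch(_iv("pain_severity", 0, 5), "root"), Branch(_iv("pain_severity", 6, 10), "t")),
            ),
            "t": TerminalNode("t", ("generic-note",)),
        })
        assert any("cycle" in f.message for f in validate_algorithm(alg).errors())

    def test_unreachable_node_flagged(self):
        alg = _alg({
            "root": TerminalNode("root", ("generic-note",)),
            "island": TerminalNode("island", ("generic-note",)),
        })
        assert any("unreachable" in f.message for f in validate_algorithm(alg).errors())

    def test_unknown_variable_and_template(self):
        alg = _alg({
            "root": DecisionNode(
                "root", "no_such_var",
                (Branch(_iv("no_such_var", 0, 5), "t"), Branch(_iv("no_such_var", 6, 10), "t")),
            ),
            "t": TerminalNode("t", ("no-such-template",)),
        })
        msgs = [f.message for f in validate_algorithm(alg).errors()]
        assert any("unknown variable" in m for m in msgs)
        assert any("unknown recommendation template" in m for m in msgs)


class TestComplexityMetrics:
    def test_single_terminal_counts(self):
        alg = single_terminal()
        assert count_decision_nodes(alg) == 0
        assert count_pathways(alg) == 1  # the empty path

    def test_two_level_binary_tree(self):
        alg = binary_two_levels()
        assert count_decision_nodes(alg) == 3
        assert count_pathways(alg) == 4

    def test_fully_crossed_three_six_two(self):
        alg = build_fully_crossed([3, 6, 2])
        assert count_decision_nodes(alg) == 1 + 3 + 18
        assert count_pathways(alg) == 36

    @pytest.mark.parametrize("widths", [[2, 2], [4, 3], [2, 3, 4], [3, 2, 2, 2]])
    def test_crossed_closed_form(self, widths):
        alg = build_fully_crossed(widths)
        paths = 1
        nodes = 0
        level_product = 1
        for w in widths:
            nodes += level_product
            level_product *= w
            paths *= w
        assert count_pathways(alg) == paths
        assert count_decision_nodes(alg) == nodes
        assert len(brute_force_paths(alg)) == paths

    def test_invalid_algorithm_refused(self):
        alg = _alg({
            "root": DecisionNode(
                "root", "pain_severity",
                (Branch(_iv("pain_severity", 1, 6), "a"), Branch(_iv("pain_severity", 7, 10), "a")),
            ),
            "a": TerminalNode("a", ("generic-note",)),
        })
        with pytest.raises(InvalidAlgorithmError):
            count_pathways(alg)


class TestRequiredVariables:
    def test_parameter_free_terminal_needs_nothing(self):
        assert required_variables(single_terminal()) == ()

    def test_pain_demo_covers_reference_case_fields(self, pain_demo, worked_cases):
        case1, _, _ = worked_cases
        req = set(required_variables(pain_demo))
        # every gating-relevant field of the reference record is demanded
        assert req <= set(case1.values) | {"medications"}
        # derived quantities are expanded to raw measurements
        assert {"sex", "age", "weight", "serum_creatinine", "medications"} <= req
        assert "creatinine_clearance" not in req
        assert "opioid_use_class" not in req

    def test_deterministic_order(self, pain_demo):
        assert list(required_variables(pain_demo)) == sorted(required_variables(pain_demo))


class TestSerialization:
    def test_round_trip_preserves_structure_and_report(self, pain_demo):
        data = algorithm_to_xml(pain_demo)
        again = algorithm_from_xml(data)
        assert validate_algorithm(again) == validate_algorithm(pain_demo)
        assert count_pathways(again) == count_pathways(pain_demo)
        assert count_decision_nodes(again) == count_decision_nodes(pain_demo)
        assert algorithm_to_xml(again) == data

    def test_malformed_document_rejected(self):
        with pytest.raises(ParseError, match="well-formed"):
            algorithm_from_xml(b"<algorithm name='x' root='r'")

    def test_schema_violation_names_location(self):
        with pytest.raises(ParseError, match="schema violation"):
            algorithm_from_xml(b"<algorithm><bogus/></algorithm>")
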