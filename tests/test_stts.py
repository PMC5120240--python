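"""Exhaustive-path testing: enumeration, boundary inputs, database, regression."""

from __future__ import annotations

from dataclasses import replace
from decimal import Decimal

import pytest

from symptomcds.algorithm_model import (
    DecisionAlgorithm,
    TerminalNode,
    count_pathways,
)
from symptomcds.calculators import creatinine_clearance
from symptomcds.rule_engine import TraversalResult, evaluate
from symptomcds.stts import (
    InfeasiblePathError,
    PathDescriptor,
    build_test_database,
    enumerate_paths,
    generate_boundary_inputs,
    run_regression,
)
from symptomcds.synthetic import build_fully_crossed, generate_random_algorithm

from oracle import brute_force_paths

D = Decimal


class TestEnumeration:
    def test_fully_crossed_three_six_two_has_36_paths(self):
        alg = build_fully_crossed([3, 6, 2])
        paths = enumerate_paths(alg)
        assert len(paths) == 36
        assert len({p.key() for p in paths}) == 36

    def test_single_terminal_yields_one_empty_path(self):
        from symptomcds.algorithm_model import standard_dictionary

        alg = DecisionAlgorithm(
            name="leaf", root="t",
            nodes={"t": TerminalNode("t", ("generic-note",))},
            dictionary=standard_dictionary(),
        )
        paths = enumerate_paths(alg)
        assert len(paths) == 1
        assert paths[0].steps == () and paths[0].terminal == "t"

    def test_matches_recursive_oracle_on_100_seeded_algorithms(self):
        """Iterative stack traversal == naive recursion, and the dynamic-
        programming pathway count == enumeration size, over 100 random DAGs."""
        for seed in range(100):
            alg = generate_random_algorithm(seed, max_depth=6, max_branching=4)
            got = {(p.steps, p.terminal) for p in enumerate_paths(alg)}
            want = {(steps, term) for steps, term in brute_force_paths(alg)}
            assert got == want, f"seed {seed}"
            assert count_pathways(alg) == len(want), f"seed {seed}"

    def test_pathway_count_matches_enumeration_for_shipped_content(self, pain_demo, fatigue_demo):
        for alg in (pain_demo, fatigue_demo):
            assert count_pathways(alg) == len(enumerate_paths(alg))


class TestBoundaryInputs:
    def test_moderate_band_pinned_at_4_6_and_interior(self, pain_demo, worked_cases):
        case1, _, _ = worked_cases
        target = evaluate(case1, pain_demo).path
        path = next(p for p in enumerate_paths(pain_demo) if p.steps == target)
        records = generate_boundary_inputs(pain_demo, path)
        severities = {r.get("pain_severity") for r in records}
        assert {D(4), D(6), D(5)} <= severities

    def test_renal_boundary_backsolved_to_30(self, pain_demo, worked_cases):
        case1, _, _ = worked_cases
        target = evaluate(case1, pain_demo).path  # runs through the >=30 band
        path = next(p for p in enumerate_paths(pain_demo) if p.steps == target)
        records = generate_boundary_inputs(pain_demo, path)
        clearances = {
            creatinine_clearance(
                r.get("sex"), r.get("age"), r.get("weight"), r.get("serum_creatinine")
            )
            for r in records
        }
        assert D("30.0") in clearances          # exactly at the band edge
        assert any(c > D(30) for c in clearances)  # and comfortably above
        assert all(c >= D(30) for c in clearances)

    def test_every_record_replays_its_path(self, pain_demo):
        for path in enumerate_paths(pain_demo)[:40]:
            for record in generate_boundary_inputs(pain_demo, path):
                result = evaluate(record, pain_demo)
                assert isinstance(result, TraversalResult)
                assert result.path == path.steps

    def test_conflicting_constraints_reported_with_nodes(self, pain_demo):
        paths = enumerate_paths(pain_demo)
        real = next(p for p in paths if len(p.steps) >= 3)
        # splice a severity step that contradicts the real first branch
        sev_step = real.steps[0]
        other_idx = (sev_step[1] + 1) % 4
        forged = PathDescriptor(
            algorithm=real.algorithm,
            steps=real.steps + ((sev_step[0], other_idx),),
            terminal=real.terminal,
        )
        with pytest.raises(InfeasiblePathError, match="severity"):
            generate_boundary_inputs(pain_demo, forged)

    def test_full_cross_supersedes_default_policy(self):
        alg = build_fully_crossed([2, 2])
        path = enumerate_paths(alg)[0]
        sparse = generate_boundary_inputs(alg, path)
        crossed = generate_boundary_inputs(alg, path, full_cross=True)
        assert len(crossed) >= len(sparse)


@pytest.fixture(scope="module")
def pain_db(pain_demo):
    return build_test_database(pain_demo)


class TestDatabase:
    def test_every_path_covered_with_zero_replay_failures(self, pain_demo, pain_db):
        cases = pain_db.cases()
        assert cases, "database must hold cases"
        covered = {tuple(c.path.steps) for c in cases}
        enumerated = {p.steps for p in enumerate_paths(pain_demo)}
        assert covered == enumerated  # union of intended paths == enumeration
        for case in cases[:50]:
            result = evaluate(case.input, pain_demo)
            assert result.path == case.path.steps

    def test_renal_impaired_query_returns_only_low_clearance(self, pain_db):
        impaired = [c for c in pain_db.cases() if "-impaired-" in c.path.terminal]
        assert impaired
        for case in impaired:
            r = case.input
            crcl = creatinine_clearance(
                r.get("sex"), r.get("age"), r.get("weight"), r.get("serum_creatinine")
            )
            assert crcl < D(30)

    def test_queryable_by_node_terminal_and_value(self, pain_db):
        by_terminal = pain_db.query(terminal="T-no-pain")
        assert by_terminal and all(c.path.terminal == "T-no-pain" for c in by_terminal)
        by_node = pain_db.query(node="use-severe")
        assert by_node and all(
            any(nid == "use-severe" for nid, _ in c.path.steps) for c in by_node
        )
        by_value = pain_db.query(variable="pain_severity", value="0")
        assert by_value and all(c.input.get("pain_severity") == D(0) for c in by_value)

    def test_rebuild_reproduces_digest(self, pain_demo, pain_db):
        again = build_test_database(pain_demo)
        assert again.digest() == pain_db.digest()

    def test_csv_export_is_flat_and_complete(self, pain_db, tmp_path):
        out = tmp_path / "cases.csv"
        pain_db.export_csv(out)
        lines = out.read_text().splitlines()
        assert len(lines) == len(pain_db.cases()) + 1  # header + one row per case


class TestRegression:
    def test_unmodified_algorithm_passes_its_own_database(self, pain_demo):
        db = build_test_database(pain_demo)
        diff = run_regression(pain_demo, db)
        assert diff.total == len(db.cases())
        assert diff.mismatches == () and diff.passed

    def test_mutated_terminal_flags_exactly_its_cases(self, pain_demo):
        db = build_test_database(pain_demo)
        # swap the dose content of one reachable terminal
        victim = "T-moderate-none-normal-somatic-none"
        mutated_nodes = dict(pain_demo.nodes)
        old = mutated_nodes[victim]
        recs = tuple(
            "naive-severe-morphine" if r == "naive-moderate-morphine" else r
            for r in old.recommendations
        )
        mutated_nodes[victim] = TerminalNode(victim, recs)
        mutated = replace(pain_demo, nodes=mutated_nodes)

        diff = run_regression(mutated, db)
        assert not diff.passed  # one mismatch fails the run
        flagged = {cid for cid, _ in diff.mismatches}
        through_victim = {c.id for c in db.cases() if c.path.terminal == victim}
        assert flagged == through_victim

    def test_database_algorithm_mismatch_rejected(self, fatigue_demo, pain_demo):
        db = build_test_database(fatigue_demo)
        with pytest.raises(ValueError, match="pain"):
            run_regression(pain_demo, db)

    def test_pending_cases_are_not_scored(self, fatigue_demo):
        db = build_test_database(fatigue_demo, validate=False)
        assert all(c.status == "pending" for c in db.cases())
        diff = run_regression(fatigue_demo, db)
        assert diff.total == 0
        promoted = db.validate_all()
        assert promoted == len(db.cases())
        assert run_regression(fatigue_demo, db).total == promoted
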