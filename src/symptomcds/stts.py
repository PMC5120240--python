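"""Stack-traversal tree-spanning (STTS) exhaustive-path testing.

The framework walks every unique root-to-terminal pathway of an algorithm
with an explicit backtracking stack, generates patient records that pin each
decision node at the boundaries of the branch the pathway selects, pairs
every generated input with the recommendations produced at build time in a
queryable relational (SQLite) test database, and regression-diffs freshly
generated recommendations against the stored expectations.  The pass bar is
100%: a single mismatch fails the run, because these recommendations steer
patient care.

Boundary policy: numeric branches contribute their two in-branch boundary
values plus one interior value at the declared resolution; categorical,
boolean and medication-class branches contribute a single representative.
Boundaries of *derived* variables (creatinine clearance) are targeted in
derived space and back-solved to raw inputs, holding demographics fixed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import sqlite3
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

from . import calculators as calc
from .algorithm_model import (
    BooleanPredicate,
    CategoryPredicate,
    DataDictionary,
    DecisionAlgorithm,
    DecisionNode,
    Interval,
    IntervalPredicate,
    MedClassPredicate,
    TerminalNode,
    VariableSpec,
    _require_valid,
)
from .records import Medication, PatientRecord
from .rule_engine import MissingDataReport, TraversalResult, evaluate

__all__ = [
    "PathDescriptor",
    "TestCase",
    "RegressionDiff",
    "InfeasiblePathError",
    "enumerate_paths",
    "generate_boundary_inputs",
    "build_test_database",
    "run_regression",
    "TestDatabase",
]

D = Decimal


class InfeasiblePathError(ValueError):
    """Contradictory constraints on one variable along a single pathway."""


@dataclass(frozen=True)
class PathDescriptor:
    algorithm: str
    steps: tuple[tuple[str, int], ...]
    terminal: str

    def key(self) -> str:
        return "/".join(f"{nid}:{idx}" for nid, idx in self.steps) or "<root>"


@dataclass(frozen=True)
class TestCase:
    id: str
    input: PatientRecord
    path: PathDescriptor
    expected: TraversalResult
    status: str = "pending"  # pending | validated


@dataclass(frozen=True)
class RegressionDiff:
    total: int
    mismatches: tuple[tuple[str, str], ...]

    @property
    def passed(self) -> bool:
        """100% agreement bar: any mismatch fails the run."""
        return not self.mismatches


# ---------------------------------------------------------------------------
# path enumeration
# ---------------------------------------------------------------------------

def enumerate_paths(alg: DecisionAlgorithm) -> list[PathDescriptor]:
    """Every unique branch sequence from root to a terminal.

    Iterative depth-first traversal with an explicit stack of not-yet-taken
    branches: follow a pathway to its end node, then pop the most recent
    untraversed branch and continue until the stack is exhausted.  Branches
    are visited in declared order, so the output order is deterministic.
    """
    _require_valid(alg)
    paths: list[PathDescriptor] = []
    stack: list[tuple[str, tuple[tuple[str, int], ...]]] = [(alg.root, ())]
    while stack:
        nid, prefix = stack.pop()
        node = alg.node(nid)
        if isinstance(node, TerminalNode):
            paths.append(PathDescriptor(alg.name, prefix, nid))
            continue
        for i in range(len(node.branches) - 1, -1, -1):
            stack.append((node.branches[i].target, prefix + ((nid, i),)))
    return paths


# ---------------------------------------------------------------------------
# boundary-input generation
# ---------------------------------------------------------------------------

#: representative 24-hour medication exposures for each opioid-use class
_CLASS_MEDS: dict[str, tuple[Medication, ...]] = {
    "none": (),
    "ir-only": (
        Medication("oxycodone", "opioid", D(10), formulation="immediate-release", dose_24h=D(40)),
    ),
    "sr-only": (
        Medication("oxycodone", "opioid", D(40), formulation="extended-release", dose_24h=D(80)),
    ),
    "ir-and-sr": (
        Medication("oxycodone", "opioid", D(10), formulation="immediate-release", dose_24h=D(40)),
        Medication("oxycodone", "opioid", D(40), formulation="extended-release", dose_24h=D(80)),
    ),
    "patch-containing": (
        Medication("fentanyl", "opioid", D(25), formulation="patch", dose_24h=D(25)),
    ),
    "non-adherent": (
        Medication("oxycodone", "opioid", D(10), formulation="immediate-release", dose_24h=D(40)),
    ),
}


def _grid_snap(spec: VariableSpec, value: Decimal, rounding=ROUND_HALF_UP) -> Decimal:
    steps = ((value - spec.lower) / spec.resolution).quantize(D(1), rounding=rounding)
    return spec.lower + steps * spec.resolution


def _interval_grid_bounds(spec: VariableSpec, iv: Interval) -> tuple[Decimal, Decimal]:
    """Smallest and largest domain-grid values inside the interval."""
    lo = max(iv.lower, spec.lower)
    if not iv.lower_closed or (lo - spec.lower) % spec.resolution != 0:
        steps = ((lo - spec.lower) / spec.resolution).to_integral_value(rounding="ROUND_FLOOR")
        lo = spec.lower + (steps + 1) * spec.resolution
    hi = min(iv.upper, spec.upper)
    if not iv.upper_closed or (hi - spec.lower) % spec.resolution != 0:
        steps = ((hi - spec.lower) / spec.resolution).to_integral_value(rounding="ROUND_CEILING")
        hi = spec.lower + (steps - 1) * spec.resolution
    if lo > hi:
        raise InfeasiblePathError(f"empty interval for {spec.name!r}")
    return lo, hi


def _numeric_targets(spec: VariableSpec, iv: Interval) -> list[Decimal]:
    """Lower boundary, upper boundary, one interior value (deduplicated)."""
    lo, hi = _interval_grid_bounds(spec, iv)
    mid = _grid_snap(spec, (lo + hi) / 2)
    out: list[Decimal] = []
    for v in (lo, hi, mid):
        if v not in out:
            out.append(v)
    return out


def _solve_clearance(target: Decimal, predicate: IntervalPredicate) -> dict[str, Any] | None:
    """Back-solve (sex, age, weight, serum creatinine) so the computed and
    rounded clearance equals ``target`` (demographics held fixed).

    Uses the same formula as the engine; the hand-computed oracle in the
    test suite cross-checks it.  Returns None when the target is outside
    the physiologically representable range.
    """
    sex, age = "male", D(67)
    for scr in (D("2.3"), D("0.9"), D("1.5"), D("4.0"), D("8.0"), D("15.0"), D("0.2")):
        base = (target * 72 * scr / (140 - age)).quantize(D("0.1"), rounding=ROUND_HALF_UP)
        for k in range(0, 11):
            for sign in (1, -1) if k else (1,):
                weight = base + sign * D(k) * D("0.1")
                if not (D(30) <= weight <= D(250)):
                    continue
                got = calc.creatinine_clearance(sex, age, weight, scr)
                if got == target and predicate.matches(got):
                    return {"sex": sex, "age": age, "weight": weight, "serum_creatinine": scr}
    return None


def _derived_numeric_records(
    spec: VariableSpec, iv: Interval, predicate: IntervalPredicate
) -> list[dict[str, Any]]:
    lo, hi = _interval_grid_bounds(spec, iv)
    span = hi - lo
    delta = min(D(10) * spec.resolution, span / 2) if span > 0 else D(0)
    candidates = [lo, hi, _grid_snap(spec, lo + delta), _grid_snap(spec, hi - delta)]
    out: list[dict[str, Any]] = []
    seen: set[Decimal] = set()
    for target in candidates:
        if target in seen:
            continue
        seen.add(target)
        solved = _solve_clearance(target, predicate)
        if solved is not None:
            out.append(solved)
        if len(out) == 3:
            break
    if not out:
        raise InfeasiblePathError(
            f"no representable raw inputs reach {spec.name!r} in [{lo}, {hi}]"
        )
    return out


def _default_values(dictionary: DataDictionary) -> dict[str, Any]:
    values: dict[str, Any] = {}
    for spec in dictionary:
        if spec.source == "computed" or spec.kind == "medication-list":
            continue
        if spec.kind == "numeric":
            values[spec.name] = _grid_snap(spec, (spec.lower + spec.upper) / 2)
        elif spec.kind == "categorical":
            values[spec.name] = spec.categories[0]
        else:
            values[spec.name] = False
    # clinically sensible anchors for the shipped dictionary
    for name, v in {
        "age": D(67), "weight": D(84), "serum_creatinine": D("0.9"),
        "sex": "male", "platelets": D(183000), "opioid_regimen_adherent": True,
        "pain_quality": "achy", "bowel_score": D(0),
    }.items():
        if name in dictionary:
            values[name] = v
    return values


@dataclass
class _Assignment:
    """One (partial) record under construction: raw values plus medications."""

    values: dict[str, Any]
    medications: tuple[Medication, ...] = ()

    def to_record(self, dictionary: DataDictionary) -> PatientRecord:
        keep = {n: v for n, v in self.values.items() if n in dictionary.names()}
        return PatientRecord(values=keep, medications=self.medications)


@dataclass
class _VarConstraint:
    """All constraints a pathway places on one variable, merged."""

    spec: VariableSpec
    nodes: list[str]
    interval: Interval | None = None
    categories: frozenset[str] | None = None
    boolean: bool | None = None
    med_classes: dict[str, bool] | None = None

    def _conflict(self) -> InfeasiblePathError:
        return InfeasiblePathError(
            f"conflicting constraints on {self.spec.name!r} at nodes {self.nodes}"
        )

    def absorb(self, predicate) -> None:
        if isinstance(predicate, IntervalPredicate):
            iv = predicate.interval
            if self.interval is None:
                self.interval = iv
            else:
                a = self.interval
                if iv.lower > a.lower or (iv.lower == a.lower and not iv.lower_closed):
                    lo, lc = iv.lower, iv.lower_closed
                else:
                    lo, lc = a.lower, a.lower_closed
                if iv.upper < a.upper or (iv.upper == a.upper and not iv.upper_closed):
                    hi, hc = iv.upper, iv.upper_closed
                else:
                    hi, hc = a.upper, a.upper_closed
                if lo > hi or (lo == hi and not (lc and hc)):
                    raise self._conflict()
                self.interval = Interval(lo, hi, lc, hc)
        elif isinstance(predicate, CategoryPredicate):
            cats = (
                predicate.categories
                if self.categories is None
                else self.categories & predicate.categories
            )
            if not cats:
                raise self._conflict()
            self.categories = cats
        elif isinstance(predicate, BooleanPredicate):
            if self.boolean is not None and self.boolean != predicate.value:
                raise self._conflict()
            self.boolean = predicate.value
        elif isinstance(predicate, MedClassPredicate):
            if self.med_classes is None:
                self.med_classes = {}
            prior = self.med_classes.get(predicate.drug_class)
            if prior is not None and prior != predicate.present:
                raise self._conflict()
            self.med_classes[predicate.drug_class] = predicate.present
        else:  # pragma: no cover - exhaustiveness guard
            raise TypeError(f"unhandled predicate {type(predicate).__name__}")

    # -- variant generation -------------------------------------------
    def variants(self, assign: _Assignment, boundary: bool) -> list[_Assignment]:
        """Assignments satisfying this merged constraint: the boundary set
        when ``boundary`` is on, otherwise a single representative."""
        spec = self.spec
        if self.interval is not None:
            if spec.source == "computed":
                if spec.name != "creatinine_clearance":
                    raise InfeasiblePathError(
                        f"no back-solver registered for computed variable {spec.name!r}"
                    )
                pred = IntervalPredicate(spec.name, self.interval)
                try:
                    solved = _derived_numeric_records(spec, self.interval, pred)
                except InfeasiblePathError:
                    raise self._conflict()
                picks = solved if boundary else [solved[-1]]
                return [replace(assign, values={**assign.values, **p}) for p in picks]
            try:
                targets = _numeric_targets(spec, self.interval)
            except InfeasiblePathError:
                raise self._conflict()
            if not boundary:
                targets = [targets[-1]]
            return [
                replace(assign, values={**assign.values, spec.name: t}) for t in targets
            ]
        if self.categories is not None:
            label = sorted(self.categories)[0]
            if spec.name == "opioid_use_class":
                meds = _CLASS_MEDS[label]
                other = tuple(m for m in assign.medications if m.drug_class != "opioid")
                return [
                    replace(
                        assign,
                        medications=other + meds,
                        values={
                            **assign.values,
                            "opioid_regimen_adherent": label != "non-adherent",
                        },
                    )
                ]
            if spec.source == "computed":
                raise InfeasiblePathError(
                    f"no back-solver registered for computed variable {spec.name!r}"
                )
            return [replace(assign, values={**assign.values, spec.name: label})]
        if self.boolean is not None:
            return [replace(assign, values={**assign.values, spec.name: self.boolean})]
        assert self.med_classes is not None
        meds = tuple(m for m in assign.medications if m.drug_class not in self.med_classes)
        for cls, present in sorted(self.med_classes.items()):
            if present:
                meds = meds + (Medication("probe", cls, D(1), dose_24h=D(1)),)
        return [replace(assign, medications=meds)]


def _merge_path_constraints(
    alg: DecisionAlgorithm, path: PathDescriptor
) -> list[_VarConstraint]:
    """Per-variable merged constraints, in first-touch path order."""
    out: dict[str, _VarConstraint] = {}
    for nid, idx in path.steps:
        node = alg.node(nid)
        if not isinstance(node, DecisionNode) or idx >= len(node.branches):
            raise InfeasiblePathError(f"path step ({nid}, {idx}) is not legal")
        var = node.variable
        if var not in out:
            out[var] = _VarConstraint(spec=alg.dictionary[var], nodes=[nid])
        else:
            out[var].nodes.append(nid)
        out[var].absorb(node.branches[idx].predicate)
    return list(out.values())


def generate_boundary_inputs(
    alg: DecisionAlgorithm,
    path: PathDescriptor,
    full_cross: bool = False,
) -> list[PatientRecord]:
    """Patient records that replay the given pathway, pinning each decision
    variable at its branch boundaries.

    Default policy: one variable is put at its boundaries at a time while
    every other constrained variable sits at an interior representative —
    full boundary coverage without the combinatorial product.
    ``full_cross=True`` takes the product of all boundary variants instead
    (exhaustive; small algorithms only).  Every returned record is replayed
    through the engine and guaranteed to traverse the intended path.
    """
    _require_valid(alg)
    constraints = _merge_path_constraints(alg, path)

    base = _Assignment(values=_default_values(alg.dictionary))
    records: list[PatientRecord] = []
    seen: set[str] = set()

    def emit(assign: _Assignment) -> None:
        rec = assign.to_record(alg.dictionary)
        key = _record_digest(rec)
        if key not in seen:
            seen.add(key)
            records.append(rec)

    if full_cross:
        counts = [len(c.variants(base, boundary=True)) for c in constraints]
        for combo in itertools.product(*[range(n) for n in counts]):
            assign = base
            for c, pick in zip(constraints, combo):
                assign = c.variants(assign, boundary=True)[pick]
            emit(assign)
    else:
        if not constraints:  # single-terminal algorithm: the empty path
            emit(base)
        for target in constraints:
            for variant in target.variants(base, boundary=True):
                assign = variant
                for other in constraints:
                    if other is target:
                        continue
                    assign = other.variants(assign, boundary=False)[0]
                emit(assign)

    for rec in records:
        result = evaluate(rec, alg)
        if isinstance(result, MissingDataReport) or result.path != path.steps:
            raise InfeasiblePathError(
                f"generated record does not replay path {path.key()!r}"
            )
    return records


# ---------------------------------------------------------------------------
# test database
# ---------------------------------------------------------------------------

def _record_to_json(rec: PatientRecord) -> str:
    def enc(v: Any) -> Any:
        if isinstance(v, Decimal):
            return {"__dec__": str(v)}
        return v

    payload = {
        "values": {k: enc(v) for k, v in sorted(rec.values.items())},
        "medications": None
        if rec.medications is None
        else [
            {
                "drug": m.drug, "drug_class": m.drug_class, "dose": str(m.dose),
                "route": m.route, "schedule": m.schedule, "formulation": m.formulation,
                "dose_24h": str(m.dose_24h),
                "tablets_per_dose": None if m.tablets_per_dose is None else str(m.tablets_per_dose),
            }
            for m in rec.medications
        ],
        "session_id": rec.session_id,
    }
    return json.dumps(payload, sort_keys=True)


def _record_from_json(data: str) -> PatientRecord:
    payload = json.loads(data)

    def dec(v: Any) -> Any:
        if isinstance(v, dict) and "__dec__" in v:
            return Decimal(v["__dec__"])
        return v

    meds = payload["medications"]
    return PatientRecord(
        values={k: dec(v) for k, v in payload["values"].items()},
        medications=None
        if meds is None
        else tuple(
            Medication(
                drug=m["drug"], drug_class=m["drug_class"], dose=Decimal(m["dose"]),
                route=m["route"], schedule=m["schedule"], formulation=m["formulation"],
                dose_24h=Decimal(m["dose_24h"]),
                tablets_per_dose=None
                if m["tablets_per_dose"] is None
                else Decimal(m["tablets_per_dose"]),
            )
            for m in meds
        ),
        session_id=payload["session_id"],
    )


def _record_digest(rec: PatientRecord) -> str:
    return hashlib.sha256(_record_to_json(rec).encode()).hexdigest()


_SCHEMA = """
CREATE TABLE IF NOT EXISTS cases (
    id TEXT PRIMARY KEY,
    algorithm TEXT NOT NULL,
    path TEXT NOT NULL,
    terminal TEXT NOT NULL,
    input TEXT NOT NULL,
    expected TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'pending'
);
CREATE TABLE IF NOT EXISTS case_values (
    case_id TEXT NOT NULL REFERENCES cases(id),
    variable TEXT NOT NULL,
    value TEXT NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_case_values ON case_values(variable, value);
"""


class TestDatabase:
    """Queryable relational store pairing inputs with expected outputs."""

    def __init__(self, path: str | Path = ":memory:"):
        self.conn = sqlite3.connect(str(path))
        self.conn.executescript(_SCHEMA)

    # -- write ---------------------------------------------------------
    def add_case(self, case: TestCase) -> None:
        self.conn.execute(
            "INSERT INTO cases (id, algorithm, path, terminal, input, expected, status)"
            " VALUES (?, ?, ?, ?, ?, ?, ?)",
            (
                case.id,
                case.path.algorithm,
                json.dumps(list(case.path.steps)),
                case.path.terminal,
                _record_to_json(case.input),
                json.dumps(case.expected.to_dict(), sort_keys=True),
                case.status,
            ),
        )
        for var, value in sorted(case.input.values.items()):
            self.conn.execute(
                "INSERT INTO case_values (case_id, variable, value) VALUES (?, ?, ?)",
                (case.id, var, str(value)),
            )
        self.conn.commit()

    def validate_all(self) -> int:
        """Promote every pending case to validated (the expert-review stand-in
        for fixture-driven test runs)."""
        cur = self.conn.execute("UPDATE cases SET status = 'validated' WHERE status = 'pending'")
        self.conn.commit()
        return cur.rowcount

    # -- read ----------------------------------------------------------
    def algorithms(self) -> list[str]:
        return [r[0] for r in self.conn.execute("SELECT DISTINCT algorithm FROM cases")]

    def cases(self, status: str | None = None) -> list[TestCase]:
        sql = "SELECT id, algorithm, path, terminal, input, expected, status FROM cases"
        args: tuple = ()
        if status is not None:
            sql += " WHERE status = ?"
            args = (status,)
        sql += " ORDER BY id"
        return [self._row_to_case(r) for r in self.conn.execute(sql, args)]

    def query(
        self,
        node: str | None = None,
        branch: int | None = None,
        terminal: str | None = None,
        variable: str | None = None,
        value: str | None = None,
    ) -> list[TestCase]:
        """Cases filtered by traversed node/branch, terminal, or input value."""
        rows = self.conn.execute(
            "SELECT id, algorithm, path, terminal, input, expected, status FROM cases ORDER BY id"
        )
        out = []
        for r in rows:
            steps = [tuple(s) for s in json.loads(r[2])]
            if terminal is not None and r[3] != terminal:
                continue
            if node is not None:
                hit = [s for s in steps if s[0] == node]
                if not hit:
                    continue
                if branch is not None and hit[0][1] != branch:
                    continue
            if variable is not None:
                val = self.conn.execute(
                    "SELECT value FROM case_values WHERE case_id = ? AND variable = ?",
                    (r[0], variable),
                ).fetchone()
                if val is None or (value is not None and val[0] != value):
                    continue
            out.append(self._row_to_case(r))
        return out

    @staticmethod
    def _row_to_case(r) -> TestCase:
        steps = tuple(tuple(s) for s in json.loads(r[2]))
        expected = json.loads(r[5])
        return TestCase(
            id=r[0],
            input=_record_from_json(r[4]),
            path=PathDescriptor(algorithm=r[1], steps=steps, terminal=r[3]),
            expected=_result_from_dict(expected),
            status=r[6],
        )

    # -- export / digest ----------------------------------------------
    def digest(self) -> str:
        h = hashlib.sha256()
        for row in self.conn.execute(
            "SELECT id, algorithm, path, terminal, input, expected, status FROM cases ORDER BY id"
        ):
            h.update(json.dumps(row, sort_keys=True).encode())
        return h.hexdigest()

    def export_csv(self, path: str | Path) -> None:
        """Flat tabular export for version-control diffing."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "algorithm", "path", "terminal", "input", "expected", "status"])
            for row in self.conn.execute(
                "SELECT id, algorithm, path, terminal, input, expected, status"
                " FROM cases ORDER BY id"
            ):
                w.writerow(row)

    def close(self) -> None:
        self.conn.close()


def _result_from_dict(d: dict) -> TraversalResult:
    from .records import RecommendationItem, RecommendationSet

    return TraversalResult(
        algorithm=d["algorithm"],
        path=tuple((nid, idx) for nid, idx in d["path"]),
        terminal=d["terminal"],
        recommendations=RecommendationSet(
            tuple(
                RecommendationItem(
                    category=i["category"], text=i["text"], fields=i["fields"]
                )
                for i in d["recommendations"]
            )
        ),
    )


def build_test_database(
    alg: DecisionAlgorithm,
    path: str | Path = ":memory:",
    full_cross: bool = False,
    validate: bool = True,
) -> TestDatabase:
    """Enumerate every pathway, generate its boundary inputs, and store each
    input paired with the recommendations generated at build time.

    Cases enter as ``pending``; ``validate=True`` promotes them immediately
    (the fixture workflow), mirroring a reviewer marking expectations good.
    Zero replay failures is a postcondition: every stored case traverses its
    intended path.
    """
    db = TestDatabase(path)
    for p_idx, pdesc in enumerate(enumerate_paths(alg)):
        inputs = generate_boundary_inputs(alg, pdesc, full_cross=full_cross)
        for v_idx, rec in enumerate(inputs):
            result = evaluate(rec, alg)
            assert isinstance(result, TraversalResult)  # replay-checked above
            db.add_case(
                TestCase(
                    id=f"{alg.name}-{p_idx:05d}-{v_idx:03d}",
                    input=rec,
                    path=pdesc,
                    expected=result,
                )
            )
    if validate:
        db.validate_all()
    return db


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def _normalise_fields(fields: dict) -> dict:
    return {k: str(v) for k, v in fields.items()}


def run_regression(alg: DecisionAlgorithm, db: TestDatabase) -> RegressionDiff:
    """Re-evaluate every validated case and diff against expectations.

    A mismatch is any difference in terminal id, recommendation count,
    category sequence, or structured dose fields.
    """
    if alg.name not in db.algorithms():
        raise ValueError(f"database holds no cases for algorithm {alg.name!r}")
    mismatches: list[tuple[str, str]] = []
    cases = db.cases(status="validated")
    for case in cases:
        result = evaluate(case.input, alg)
        if isinstance(result, MissingDataReport):
            mismatches.append((case.id, f"insufficient data: {result.missing}"))
            continue
        exp = case.expected
        if result.terminal != exp.terminal:
            mismatches.append((case.id, f"terminal {exp.terminal} -> {result.terminal}"))
            continue
        got_items = list(result.recommendations)
        exp_items = list(exp.recommendations)
        if len(got_items) != len(exp_items):
            mismatches.append(
                (case.id, f"recommendation count {len(exp_items)} -> {len(got_items)}")
            )
            continue
        for i, (g, e) in enumerate(zip(got_items, exp_items)):
            if g.category != e.category:
                mismatches.append((case.id, f"item {i} category {e.category} -> {g.category}"))
                break
            if _normalise_fields(dict(g.fields)) != _normalise_fields(dict(e.fields)):
                mismatches.append((case.id, f"item {i} dose fields differ"))
                break
    return RegressionDiff(total=len(cases), mismatches=tuple(mismatches))
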