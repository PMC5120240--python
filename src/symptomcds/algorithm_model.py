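"""Declarative model of branching clinical algorithms.

An algorithm is a rooted directed acyclic graph.  Interior *decision nodes*
branch two or more ways on a single clinical variable; *terminal nodes*
carry the care recommendations for their pathway.  A shared sub-block (for
example a renal-function check) may be referenced from several graph
positions; complexity metrics count each distinct position.

The validator makes the consistency checks mechanical: branch predicates at
every node must be pairwise disjoint and jointly cover the variable's
declared domain, so a validated algorithm can never dead-end or face an
ambiguous branch at run time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from functools import lru_cache
from typing import Any, Iterable, Iterator, Mapping

import networkx as nx

from .records import Medication, as_decimal
from .templates import known_template, template_requires

__all__ = [
    "VariableSpec",
    "DataDictionary",
    "Interval",
    "Predicate",
    "IntervalPredicate",
    "CategoryPredicate",
    "BooleanPredicate",
    "MedClassPredicate",
    "Branch",
    "DecisionNode",
    "TerminalNode",
    "DecisionAlgorithm",
    "Finding",
    "ValidationReport",
    "InvalidAlgorithmError",
    "validate_algorithm",
    "count_decision_nodes",
    "count_pathways",
    "required_variables",
    "standard_dictionary",
]

VARIABLE_KINDS = ("numeric", "categorical", "boolean", "medication-list")
VARIABLE_SOURCES = ("patient-reported", "chart", "computed")


# ---------------------------------------------------------------------------
# data dictionary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one clinical variable.

    Numeric variables carry a closed interval domain with a resolution (the
    grid step at which values are clinically meaningful); categorical
    variables an enumerated label set.  ``source='computed'`` marks derived
    quantities (e.g. creatinine clearance) whose raw ``inputs`` are what the
    completeness gate actually demands.
    """

    name: str
    kind: str
    lower: Decimal | None = None
    upper: Decimal | None = None
    resolution: Decimal | None = None
    categories: tuple[str, ...] = ()
    units: str = ""
    source: str = "patient-reported"
    inputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.source not in VARIABLE_SOURCES:
            raise ValueError(f"unknown variable source {self.source!r}")
        if self.kind == "numeric":
            if self.lower is None or self.upper is None or self.resolution is None:
                raise ValueError(f"numeric variable {self.name!r} needs lower/upper/resolution")
            if not self.lower < self.upper:
                raise ValueError(f"numeric domain of {self.name!r} needs lower < upper")
            if self.resolution <= 0:
                raise ValueError(f"resolution of {self.name!r} must be positive")
        if self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"categorical variable {self.name!r} needs categories")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"duplicate categories on {self.name!r}")
        if self.source == "computed" and not self.inputs:
            raise ValueError(f"computed variable {self.name!r} must declare inputs")

    def grid(self) -> Iterator[Decimal]:
        """All domain values at declared resolution (numeric only)."""
        assert self.kind == "numeric"
        v = self.lower
        while v <= self.upper:
            yield v
            v += self.resolution

    def in_domain(self, value: Any) -> bool:
        if self.kind == "numeric":
            v = as_decimal(value)
            return self.lower <= v <= self.upper
        if self.kind == "categorical":
            return value in self.categories
        if self.kind == "boolean":
            return isinstance(value, bool)
        return all(isinstance(m, Medication) for m in value)


class DataDictionary:
    """Uniquely named variable specs; every predicate must resolve here."""

    def __init__(self, variables: Iterable[VariableSpec]):
        self._vars: dict[str, VariableSpec] = {}
        for v in variables:
            if v.name in self._vars:
                raise ValueError(f"duplicate variable name {v.name!r}")
            self._vars[v.name] = v

    def __contains__(self, name: str) -> bool:
        return name in self._vars

    def __getitem__(self, name: str) -> VariableSpec:
        return self._vars[name]

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self._vars.values())

    def names(self) -> tuple[str, ...]:
        return tuple(self._vars)

    def raw_inputs(self, name: str) -> tuple[str, ...]:
        """Expand a (possibly computed) variable to its raw input variables."""
        spec = self._vars.get(name)
        if spec is None or spec.source != "computed":
            return (name,)
        out: list[str] = []
        for inp in spec.inputs:
            for raw in self.raw_inputs(inp):
                if raw not in out:
                    out.append(raw)
        return tuple(out)


# ---------------------------------------------------------------------------
# predicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    lower: Decimal
    upper: Decimal
    lower_closed: bool = True
    upper_closed: bool = True

    def contains(self, value: Decimal) -> bool:
        lo = value >= self.lower if self.lower_closed else value > self.lower
        hi = value <= self.upper if self.upper_closed else value < self.upper
        return lo and hi


@dataclass(frozen=True)
class Predicate:
    variable: str

    def matches(self, value: Any) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class IntervalPredicate(Predicate):
    interval: Interval = None  # type: ignore[assignment]

    def matches(self, value: Any) -> bool:
        return self.interval.contains(as_decimal(value))


@dataclass(frozen=True)
class CategoryPredicate(Predicate):
    categories: frozenset[str] = frozenset()

    def matches(self, value: Any) -> bool:
        return value in self.categories


@dataclass(frozen=True)
class BooleanPredicate(Predicate):
    value: bool = True

    def matches(self, value: Any) -> bool:
        return bool(value) is self.value


@dataclass(frozen=True)
class MedClassPredicate(Predicate):
    drug_class: str = ""
    present: bool = True

    def matches(self, value: Any) -> bool:
        has = any(m.drug_class == self.drug_class for m in value)
        return has is self.present


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    predicate: Predicate
    target: str


@dataclass(frozen=True)
class DecisionNode:
    id: str
    variable: str
    branches: tuple[Branch, ...]


@dataclass(frozen=True)
class TerminalNode:
    id: str
    recommendations: tuple[str, ...]


@dataclass(frozen=True)
class DecisionAlgorithm:
    name: str
    root: str
    nodes: Mapping[str, DecisionNode | TerminalNode]
    dictionary: DataDictionary

    def node(self, node_id: str) -> DecisionNode | TerminalNode:
        return self.nodes[node_id]

    def reachable_ids(self) -> tuple[str, ...]:
        """Node ids reachable from the root, in deterministic DFS preorder."""
        seen: list[str] = []
        seen_set: set[str] = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen_set or nid not in self.nodes:
                continue
            seen.append(nid)
            seen_set.add(nid)
            node = self.nodes[nid]
            if isinstance(node, DecisionNode):
                stack.extend(b.target for b in reversed(node.branches))
        return tuple(seen)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for nid, node in self.nodes.items():
            if isinstance(node, DecisionNode):
                for b in node.branches:
                    if b.target in self.nodes:
                        g.add_edge(nid, b.target)
        return g


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    node_id: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity == "error")


class InvalidAlgorithmError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        msgs = "; ".join(f"{f.node_id}: {f.message}" for f in report.errors())
        super().__init__(f"algorithm failed validation: {msgs}")


def _domain_points(spec: VariableSpec, node: DecisionNode) -> list[Any] | None:
    """Atomic domain values to scan for disjointness/exhaustiveness.

    Medication-list branching is presence/absence of one drug class, so its
    scan space is a synthetic present/absent pair for that class.
    """
    if spec.kind == "numeric":
        return list(spec.grid())
    if spec.kind == "categorical":
        return list(spec.categories)
    if spec.kind == "boolean":
        return [True, False]
    classes = {
        b.predicate.drug_class
        for b in node.branches
        if isinstance(b.predicate, MedClassPredicate)
    }
    if len(classes) != 1:
        return None  # reported separately
    cls = classes.pop()
    present = (Medication(drug="probe", drug_class=cls, dose=Decimal(0)),)
    return [present, ()]


def validate_algorithm(alg: DecisionAlgorithm) -> ValidationReport:
    """Check structural and logical consistency; problems are findings,
    never exceptions, so a report can list every defect at once."""
    findings: list[Finding] = []
    err = lambda nid, msg: findings.append(Finding("error", nid, msg))

    if alg.root not in alg.nodes:
        err(alg.root, "root node does not exist")
        return ValidationReport(tuple(findings))

    g = alg.to_digraph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        err(cycle[0][0], f"cycle detected: {' -> '.join(e[0] for e in cycle)}")

    reachable = set(alg.reachable_ids())
    for nid in alg.nodes:
        if nid not in reachable:
            err(nid, "node unreachable from root")

    for nid, node in alg.nodes.items():
        if isinstance(node, TerminalNode):
            if not node.recommendations:
                err(nid, "terminal with no recommendation")
            for tid in node.recommendations:
                if not known_template(tid):
                    err(nid, f"unknown recommendation template {tid!r}")
            continue

        if len(node.branches) < 2:
            err(nid, "decision node must branch in two or more directions")
        for b in node.branches:
            if b.target not in alg.nodes:
                err(nid, f"dangling successor {b.target!r}")
            if b.predicate.variable != node.variable:
                err(nid, f"predicate variable {b.predicate.variable!r} differs from node variable")

        if node.variable not in alg.dictionary:
            err(nid, f"unknown variable {node.variable!r}")
            continue
        spec = alg.dictionary[node.variable]

        # interval bounds must lie within the declared domain
        for b in node.branches:
            p = b.predicate
            if isinstance(p, IntervalPredicate) and spec.kind == "numeric":
                if p.interval.lower < spec.lower or p.interval.upper > spec.upper:
                    err(nid, f"interval bounds outside domain of {node.variable!r}")
            if isinstance(p, CategoryPredicate) and spec.kind == "categorical":
                bad = p.categories - set(spec.categories)
                if bad:
                    err(nid, f"unknown categories {sorted(bad)!r} for {node.variable!r}")

        points = _domain_points(spec, node)
        if points is None:
            err(nid, "medication-list branches must test a single drug class")
            continue
        uncovered = 0
        overlapped = 0
        for value in points:
            hits = sum(1 for b in node.branches if b.predicate.matches(value))
            if hits == 0:
                uncovered += 1
            elif hits > 1:
                overlapped += 1
        if uncovered:
            err(nid, f"non-exhaustive branches: {uncovered} domain value(s) uncovered")
        if overlapped:
            err(nid, f"overlapping branches: {overlapped} domain value(s) matched twice")

    # computed variables must expand to dictionary members
    for spec in alg.dictionary:
        if spec.source == "computed":
            for inp in spec.inputs:
                if inp not in alg.dictionary:
                    err("dictionary", f"computed variable {spec.name!r} input {inp!r} unknown")

    return ValidationReport(tuple(findings))


def _require_valid(alg: DecisionAlgorithm) -> None:
    """Raise unless the algorithm validates; memoized per instance so the
    domain scan runs once however many operations touch the algorithm."""
    report = alg.__dict__.get("_validation_memo")
    if report is None:
        report = validate_algorithm(alg)
        object.__setattr__(alg, "_validation_memo", report)
    if not report.ok:
        raise InvalidAlgorithmError(report)


# ---------------------------------------------------------------------------
# complexity metrics
# ---------------------------------------------------------------------------

def count_decision_nodes(alg: DecisionAlgorithm) -> int:
    """Number of decision-node instances (distinct graph positions).

    A clinical parameter appearing at k distinct positions contributes k,
    so a renal check referenced from several branches counts once per
    position it occupies.
    """
    _require_valid(alg)
    return sum(
        1 for nid in alg.reachable_ids() if isinstance(alg.nodes[nid], DecisionNode)
    )


def count_pathways(alg: DecisionAlgorithm) -> int:
    """Number of distinct root-to-terminal branch sequences.

    Computed by dynamic programming over the DAG; agrees with the exhaustive
    stack-based enumeration by construction (tested against it).
    """
    _require_valid(alg)

    memo: dict[str, int] = {}

    order = list(nx.topological_sort(alg.to_digraph()))
    for nid in reversed(order):
        node = alg.nodes[nid]
        if isinstance(node, TerminalNode):
            memo[nid] = 1
        else:
            memo[nid] = sum(memo[b.target] for b in node.branches)
    return memo[alg.root]


def required_variables(alg: DecisionAlgorithm) -> tuple[str, ...]:
    """Raw variables any reachable predicate or template binding reads.

    Computed variables are expanded to their raw inputs: the completeness
    gate demands the measurements, not the derived quantity.  Order is
    deterministic (sorted) for stable serialization.
    """
    _require_valid(alg)
    out: set[str] = set()
    for nid in alg.reachable_ids():
        node = alg.nodes[nid]
        if isinstance(node, DecisionNode):
            out.update(alg.dictionary.raw_inputs(node.variable))
        else:
            for tid in node.recommendations:
                for var in template_requires(tid):
                    out.update(alg.dictionary.raw_inputs(var))
    return tuple(sorted(out))


# ---------------------------------------------------------------------------
# the shipped data dictionary
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def standard_dictionary() -> DataDictionary:
    """The concrete clinical data dictionary used by the shipped content.

    Minimal set covering the pain algorithm's factor list (pain
    characteristics, current therapy, medical variables, opioid-induced
    constipation) plus the generic symptom severities: patient-reported 0-10
    symptom scores, a 0-4 constipation score, demographics, renal labs,
    platelets, history flags, and the medication list.
    """
    D = Decimal
    return DataDictionary(
        [
            VariableSpec("pain_severity", "numeric", D(0), D(10), D(1), units="0-10 self-report"),
            VariableSpec("anxiety_severity", "numeric", D(0), D(10), D(1), units="0-10 self-report"),
            VariableSpec("depression_severity", "numeric", D(0), D(10), D(1), units="0-10 self-report"),
            VariableSpec("dyspnea_severity", "numeric", D(0), D(10), D(1), units="0-10 self-report"),
            VariableSpec("fatigue_severity", "numeric", D(0), D(10), D(1), units="0-10 self-report"),
            VariableSpec("bowel_score", "numeric", D(0), D(4), D(1), units="0-4 constipation score"),
            VariableSpec(
                "pain_quality",
                "categorical",
                categories=("achy", "sharp", "burning", "shooting", "other"),
            ),
            VariableSpec("pain_timing", "categorical", categories=("intermittent", "constant")),
            VariableSpec("age", "numeric", D(21), D(110), D(1), units="years", source="chart"),
            VariableSpec("weight", "numeric", D(30), D(250), D("0.1"), units="kg", source="chart"),
            VariableSpec("sex", "categorical", categories=("male", "female"), source="chart"),
            VariableSpec(
                "serum_creatinine", "numeric", D("0.2"), D("15.0"), D("0.1"),
                units="mg/dL", source="chart",
            ),
            VariableSpec(
                "platelets", "numeric", D(0), D(2000000), D(1000),
                units="count/mL", source="chart",
            ),
            VariableSpec("gi_bleed_history", "boolean", source="chart"),
            VariableSpec("alcohol_use", "boolean"),
            VariableSpec("opioid_regimen_adherent", "boolean"),
            VariableSpec("medications", "medication-list", source="chart"),
            VariableSpec(
                "creatinine_clearance", "numeric", D(0), D(3000), D("0.1"),
                units="mL/min", source="computed",
                inputs=("sex", "age", "weight", "serum_creatinine"),
            ),
            VariableSpec(
                "opioid_use_class", "categorical",
                categories=(
                    "none", "ir-only", "sr-only", "ir-and-sr",
                    "patch-containing", "non-adherent",
                ),
                source="computed",
                inputs=("medications", "opioid_regimen_adherent"),
            ),
        ]
    )
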