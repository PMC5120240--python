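"""Evaluation of patient records against validated algorithms.

Evaluation is all-or-nothing: complete traversal of every decision node is
required for correct recommendations, so an algorithm runs only if every
variable it could possibly read is present.  A record with missing data gets
a :class:`MissingDataReport` naming exactly what is absent — never partial
recommendations.

Derived quantities (creatinine clearance, the 24-hour opioid-use class) are
computed on demand during traversal and cached per evaluation; the gate
checks their raw inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Any, Sequence

from . import calculators
from .algorithm_model import (
    DataDictionary,
    DecisionAlgorithm,
    DecisionNode,
    _require_valid,
    required_variables,
)
from .records import PatientRecord, RecommendationSet
from .templates import get_template

__all__ = [
    "MissingDataReport",
    "TraversalResult",
    "EvaluationContext",
    "DomainError",
    "InternalConsistencyError",
    "ConfigurationError",
    "check_completeness",
    "evaluate",
    "evaluate_all",
]

#: explicit refusals count as absent: a declined answer cannot steer a branch
MISSING_SENTINELS = (None, "declined")


class DomainError(ValueError):
    """A present value lies outside its declared domain."""


class InternalConsistencyError(RuntimeError):
    """No (or multiple) matching branch during traversal — impossible for a
    validated algorithm, so this signals a validator defect, not bad data."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MissingDataReport:
    """Insufficient-data outcome: the variables that blocked the run."""

    algorithm: str
    missing: tuple[str, ...]

    @property
    def message(self) -> str:
        return (
            f"The available data were insufficient to run the {self.algorithm} "
            f"algorithm; missing: {', '.join(self.missing)}."
        )

    def to_dict(self) -> dict[str, Any]:
        return {"algorithm": self.algorithm, "missing": list(self.missing)}


@dataclass(frozen=True)
class TraversalResult:
    algorithm: str
    path: tuple[tuple[str, int], ...]
    terminal: str
    recommendations: RecommendationSet

    def to_dict(self) -> dict[str, Any]:
        return {
            "algorithm": self.algorithm,
            "path": [[nid, idx] for nid, idx in self.path],
            "terminal": self.terminal,
            "recommendations": [
                {
                    "category": i.category,
                    "text": i.text,
                    "fields": {k: _jsonable(v) for k, v in i.fields.items()},
                }
                for i in self.recommendations
            ],
        }


def _jsonable(v: Any) -> Any:
    return str(v) if isinstance(v, Decimal) else v


@dataclass
class EvaluationContext:
    """What a template binding may read: the record, the cached derived
    values, and where in the graph the traversal stands."""

    record: PatientRecord
    dictionary: DataDictionary
    derived: dict[str, Any] = field(default_factory=dict)
    path: tuple[tuple[str, int], ...] = ()

    def value(self, name: str) -> Any:
        spec = self.dictionary[name]
        if spec.kind == "medication-list":
            return self.record.medications
        if spec.source == "computed":
            if name not in self.derived:
                self.derived[name] = _derive(name, self)
            return self.derived[name]
        return self.record.get(name)


# ---------------------------------------------------------------------------
# derived variables
# ---------------------------------------------------------------------------

def _derive_creatinine_clearance(ctx: EvaluationContext) -> Decimal:
    return calculators.creatinine_clearance(
        ctx.value("sex"), ctx.value("age"), ctx.value("weight"), ctx.value("serum_creatinine")
    )


def _derive_opioid_use_class(ctx: EvaluationContext) -> str:
    opioids = [m for m in ctx.record.medications if m.drug_class == "opioid"]
    if not opioids:
        return "none"
    if not ctx.value("opioid_regimen_adherent"):
        return "non-adherent"
    forms = {m.formulation for m in opioids}
    if "patch" in forms:
        return "patch-containing"
    has_ir = "immediate-release" in forms
    has_sr = "extended-release" in forms
    if has_ir and has_sr:
        return "ir-and-sr"
    if has_sr:
        return "sr-only"
    return "ir-only"


_DERIVATIONS = {
    "creatinine_clearance": _derive_creatinine_clearance,
    "opioid_use_class": _derive_opioid_use_class,
}


def _derive(name: str, ctx: EvaluationContext) -> Any:
    try:
        fn = _DERIVATIONS[name]
    except KeyError:
        raise ConfigurationError(f"no derivation registered for computed variable {name!r}")
    return fn(ctx)


# ---------------------------------------------------------------------------
# gating and traversal
# ---------------------------------------------------------------------------

def _present(patient: PatientRecord, dictionary: DataDictionary, name: str) -> bool:
    if name in dictionary and dictionary[name].kind == "medication-list":
        return patient.medications is not None
    return name in patient.values and patient.values[name] not in MISSING_SENTINELS


def check_completeness(patient: PatientRecord, alg: DecisionAlgorithm) -> MissingDataReport:
    """All-or-nothing gate: every required raw variable must be present.

    An empty ``missing`` list means the algorithm may run.
    """
    missing = tuple(
        sorted(
            name
            for name in required_variables(alg)
            if not _present(patient, alg.dictionary, name)
        )
    )
    return MissingDataReport(algorithm=alg.name, missing=missing)


def _check_domains(patient: PatientRecord, alg: DecisionAlgorithm) -> None:
    for name in required_variables(alg):
        spec = alg.dictionary[name] if name in alg.dictionary else None
        if spec is None or spec.kind == "medication-list":
            continue
        value = patient.get(name)
        if not spec.in_domain(value):
            raise DomainError(f"value {value!r} of {name!r} outside declared domain")


def evaluate(
    patient: PatientRecord, alg: DecisionAlgorithm
) -> TraversalResult | MissingDataReport:
    """Traverse one algorithm for one patient.

    Returns exactly one of a :class:`TraversalResult` (complete path plus
    fully rendered recommendations) or a :class:`MissingDataReport`.
    """
    from .content import render_recommendation  # local import: content builds on engine types

    _require_valid(alg)
    gate = check_completeness(patient, alg)
    if gate.missing:
        return gate
    _check_domains(patient, alg)

    ctx = EvaluationContext(record=patient, dictionary=alg.dictionary)
    path: list[tuple[str, int]] = []
    nid = alg.root
    node = alg.node(nid)
    while isinstance(node, DecisionNode):
        value = ctx.value(node.variable)
        hits = [i for i, b in enumerate(node.branches) if b.predicate.matches(value)]
        if len(hits) != 1:
            raise InternalConsistencyError(
                f"{len(hits)} branches matched {node.variable}={value!r} at node {nid!r}"
            )
        idx = hits[0]
        path.append((nid, idx))
        nid = node.branches[idx].target
        node = alg.node(nid)

    ctx.path = tuple(path)
    items = []
    for tid in node.recommendations:
        rendered = render_recommendation(get_template(tid), ctx)
        if rendered is not None:
            items.append(rendered)
    return TraversalResult(
        algorithm=alg.name,
        path=tuple(path),
        terminal=nid,
        recommendations=RecommendationSet(tuple(items)),
    )


def evaluate_all(
    patient: PatientRecord, algs: Sequence[DecisionAlgorithm]
) -> dict[str, TraversalResult | MissingDataReport]:
    """Run several algorithms independently; one algorithm's missing data
    never blocks another.  Result order follows input order."""
    names = [a.name for a in algs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate algorithm names: {names}")
    return {a.name: evaluate(patient, a) for a in algs}


def replay_path(
    patient: PatientRecord, alg: DecisionAlgorithm
) -> tuple[tuple[str, int], ...]:
    """Branch sequence a record would traverse (no rendering); gate must pass."""
    result = evaluate(patient, alg)
    if isinstance(result, MissingDataReport):
        raise DomainError(f"cannot replay an incomplete record: {result.missing}")
    return result.path
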