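"""Seeded generators: patient cohorts, random algorithms, shipped fixtures.

Everything here is a pure function of its seed and spec, with per-component
substreams derived by hashing, so adding one generator never perturbs the
output of another and serialized output is reproducible across platforms.

Also packages the two fully specified reference cases the pain content is
calibrated against (an opioid-naïve moderate-pain visit and an
opioid-tolerant severe-pain visit with renal impairment), with their
expected recommendation sets as structured field data, plus ten synthetic
integration cases spanning every shipped algorithm.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import random
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Any, Mapping, Sequence

from . import content as _content  # noqa: F401  (registers the template library)
from .algorithm_model import (
    Branch,
    DataDictionary,
    DecisionAlgorithm,
    DecisionNode,
    Interval,
    IntervalPredicate,
    BooleanPredicate,
    CategoryPredicate,
    TerminalNode,
    VariableSpec,
    standard_dictionary,
    validate_algorithm,
)
from .records import Medication, PatientRecord

__all__ = [
    "CohortSpec",
    "generate_patient_cohort",
    "generate_random_algorithm",
    "build_fully_crossed",
    "worked_case_fixtures",
    "integration_fixtures",
]

D = Decimal


def _substream(seed: int, *tags) -> random.Random:
    """Independent RNG derived from (seed, tags) by hashing — stable across
    platforms and insensitive to generator call order."""
    digest = hashlib.sha256(repr((int(seed),) + tags).encode()).digest()
    return random.Random(int.from_bytes(digest[:8], "big"))


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic cohort.

    ``completeness`` is the probability each variable is present (a mapping
    gives per-variable overrides); ``severity_mix`` weights the green /
    yellow / red symptom bands and must sum to 1.
    """

    n: int
    seed: int
    completeness: float = 1.0
    per_variable_completeness: Mapping[str, float] = field(default_factory=dict)
    severity_mix: tuple[float, float, float] = (0.4, 0.35, 0.25)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        probs = [self.completeness, *self.per_variable_completeness.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("completeness probabilities must lie in [0, 1]")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError("severity mix weights must sum to 1")


_SEVERITY_BANDS = ((0, 3), (4, 6), (7, 10))

#: plausible 24-hour opioid exposures a synthetic patient may carry
_OPIOID_CHOICES: tuple[tuple[Medication, ...], ...] = (
    (),
    (),
    (Medication("oxycodone", "opioid", D(10), formulation="immediate-release", dose_24h=D(40)),),
    (Medication("morphine", "opioid", D(30), formulation="extended-release", dose_24h=D(60)),),
    (
        Medication("oxycodone", "opioid", D(15), formulation="immediate-release", dose_24h=D(90)),
        Medication("oxycodone", "opioid", D(60), formulation="extended-release", dose_24h=D(120)),
    ),
    (Medication("fentanyl", "opioid", D(25), formulation="patch", dose_24h=D(25)),),
)


def _grid_choice(rng: random.Random, spec: VariableSpec) -> Decimal:
    n_steps = int((spec.upper - spec.lower) / spec.resolution)
    return spec.lower + rng.randint(0, n_steps) * spec.resolution


def generate_patient_cohort(
    spec: CohortSpec, dictionary: DataDictionary | None = None
) -> list[PatientRecord]:
    """Synthetic patient records with every value inside its domain.

    Symptom scores follow the band mix; labs and demographics are uniform on
    their grids; each variable is then kept with its completeness
    probability.  Reproducible for a fixed seed.
    """
    dictionary = dictionary or standard_dictionary()
    cohort: list[PatientRecord] = []
    for i in range(spec.n):
        rng = _substream(spec.seed, "cohort", i)
        values: dict[str, Any] = {}
        for var in dictionary:
            if var.source == "computed" or var.kind == "medication-list":
                continue
            if var.name.endswith("_severity"):
                lo, hi = rng.choices(_SEVERITY_BANDS, weights=spec.severity_mix)[0]
                values[var.name] = D(rng.randint(lo, hi))
            elif var.kind == "numeric":
                values[var.name] = _grid_choice(rng, var)
            elif var.kind == "categorical":
                values[var.name] = rng.choice(var.categories)
            else:
                values[var.name] = rng.random() < 0.2
        # adherence flag skews positive; serum creatinine skews normal-ish
        values["opioid_regimen_adherent"] = rng.random() < 0.9
        values["serum_creatinine"] = D(rng.randint(4, 40)) / 10
        medications = rng.choice(_OPIOID_CHOICES)

        for name in list(values):
            p = spec.per_variable_completeness.get(name, spec.completeness)
            if rng.random() >= p:
                del values[name]
        p_meds = spec.per_variable_completeness.get("medications", spec.completeness)
        if rng.random() >= p_meds:
            medications = None

        cohort.append(
            PatientRecord(
                values=values,
                medications=medications,
                visit_date=_dt.date(2015, 1, 1) + _dt.timedelta(days=i % 365),
                session_id=f"S{spec.seed:05d}-{i:04d}",
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# random algorithms (oracle substrate for exhaustive-path testing)
# ---------------------------------------------------------------------------

#: variables random algorithms may branch on: raw, with small scan grids
_RANDOM_VAR_POOL = (
    "pain_severity",
    "anxiety_severity",
    "depression_severity",
    "dyspnea_severity",
    "fatigue_severity",
    "bowel_score",
    "pain_quality",
    "pain_timing",
    "sex",
    "gi_bleed_history",
    "alcohol_use",
)


def _partition_numeric(rng: random.Random, spec: VariableSpec, k: int) -> list[Interval]:
    """Split a numeric domain into k contiguous grid-aligned intervals."""
    n_steps = int((spec.upper - spec.lower) / spec.resolution)
    cuts = sorted(rng.sample(range(1, n_steps + 1), k - 1))
    bounds = [0, *cuts, n_steps + 1]
    out = []
    for a, b in zip(bounds, bounds[1:]):
        lo = spec.lower + a * spec.resolution
        hi = spec.lower + (b - 1) * spec.resolution
        out.append(Interval(lo, hi))
    return out


def generate_random_algorithm(
    seed: int,
    max_depth: int = 4,
    max_branching: int = 4,
    dictionary: DataDictionary | None = None,
) -> DecisionAlgorithm:
    """Random valid algorithm: partitioning, exhaustive branches throughout,
    with occasional merge points so the graph is a DAG rather than a tree.

    The generator's contract is that its output always validates; the test
    suite holds it to that.
    """
    if max_depth < 1 or max_branching < 2:
        raise ValueError("need max_depth >= 1 and max_branching >= 2")
    dictionary = dictionary or standard_dictionary()
    rng = _substream(seed, "alg")
    nodes: dict[str, DecisionNode | TerminalNode] = {}
    counter = {"n": 0, "t": 0}
    #: nodes eligible for reuse as merge targets, keyed by level
    pool: dict[int, list[str]] = {}

    def new_terminal() -> str:
        tid = f"t{counter['t']}"
        counter["t"] += 1
        nodes[tid] = TerminalNode(id=tid, recommendations=("generic-note",))
        return tid

    def new_node(level: int) -> str:
        if level >= max_depth:
            return new_terminal()
        var_name = rng.choice(_RANDOM_VAR_POOL)
        spec = dictionary[var_name]
        if spec.kind == "boolean":
            k = 2
        elif spec.kind == "categorical":
            k = rng.randint(2, min(max_branching, len(spec.categories)))
        else:
            n_steps = int((spec.upper - spec.lower) / spec.resolution)
            k = rng.randint(2, min(max_branching, n_steps + 1))

        if spec.kind == "boolean":
            preds = [BooleanPredicate(var_name, True), BooleanPredicate(var_name, False)]
        elif spec.kind == "categorical":
            cats = list(spec.categories)
            rng.shuffle(cats)
            splits = sorted(rng.sample(range(1, len(cats)), k - 1))
            groups = [cats[a:b] for a, b in zip([0, *splits], [*splits, len(cats)])]
            preds = [CategoryPredicate(var_name, frozenset(g)) for g in groups]
        else:
            preds = [
                IntervalPredicate(var_name, iv)
                for iv in _partition_numeric(rng, spec, k)
            ]

        branches = []
        for p in preds:
            deeper = [nid for lvl, ids in pool.items() if lvl > level for nid in ids]
            if level + 1 < max_depth and deeper and rng.random() < 0.2:
                target = rng.choice(sorted(deeper))  # merge point
            elif level + 1 >= max_depth or rng.random() < 0.25:
                target = new_terminal()
            else:
                target = new_node(level + 1)
            branches.append(Branch(p, target))
        nid = f"n{counter['n']}"
        counter["n"] += 1
        nodes[nid] = DecisionNode(id=nid, variable=var_name, branches=tuple(branches))
        pool.setdefault(level, []).append(nid)
        return nid

    root = new_node(0)
    alg = DecisionAlgorithm(
        name=f"random-{seed}", root=root, nodes=nodes, dictionary=dictionary
    )
    report = validate_algorithm(alg)
    assert report.ok, f"generator produced an invalid algorithm: {report.findings}"
    return alg


_CROSSED_LEVEL_VARS = (
    "pain_severity",
    "fatigue_severity",
    "anxiety_severity",
    "depression_severity",
    "dyspnea_severity",
)


def build_fully_crossed(widths: Sequence[int]) -> DecisionAlgorithm:
    """Fully crossed tree with the given branch width per level.

    Level i branches its symptom variable into ``widths[i]`` contiguous
    bands; every combination of bands gets its own terminal, so the pathway
    count is the product of the widths and the decision-node count is
    1 + w1 + w1*w2 + ...
    """
    if not widths or any(w < 2 for w in widths):
        raise ValueError("each level needs width >= 2")
    if len(widths) > len(_CROSSED_LEVEL_VARS):
        raise ValueError(f"at most {len(_CROSSED_LEVEL_VARS)} levels supported")
    dictionary = standard_dictionary()
    nodes: dict[str, DecisionNode | TerminalNode] = {}
    counter = {"n": 0, "t": 0}

    def build(level: int) -> str:
        if level == len(widths):
            tid = f"t{counter['t']}"
            counter["t"] += 1
            nodes[tid] = TerminalNode(id=tid, recommendations=("generic-note",))
            return tid
        var = _CROSSED_LEVEL_VARS[level]
        spec = dictionary[var]
        w = widths[level]
        n_steps = int((spec.upper - spec.lower) / spec.resolution)
        cuts = [round((i * (n_steps + 1)) / w) for i in range(w + 1)]
        branches = []
        for a, b in zip(cuts, cuts[1:]):
            iv = Interval(
                spec.lower + a * spec.resolution, spec.lower + (b - 1) * spec.resolution
            )
            branches.append(Branch(IntervalPredicate(var, iv), build(level + 1)))
        nid = f"n{counter['n']}"
        counter["n"] += 1
        nodes[nid] = DecisionNode(id=nid, variable=var, branches=tuple(branches))
        return nid

    root = build(0)
    return DecisionAlgorithm(
        name="crossed-" + "x".join(map(str, widths)), root=root, nodes=nodes,
        dictionary=dictionary,
    )


# ---------------------------------------------------------------------------
# shipped reference fixtures
# ---------------------------------------------------------------------------

def worked_case_fixtures() -> tuple[PatientRecord, PatientRecord, dict[str, tuple[dict, ...]]]:
    """The two reference visits the pain content is calibrated against.

    Case 1: moderate (6/10) intermittent achy pain, opioid-naïve, normal
    renal function, no constipation.  Case 2: severe (8/10) constant burning
    pain on immediate- plus extended-release oxycodone (24-h use 90 + 120
    mg), renally impaired, grade-2 constipation on sennosides.  Expected
    recommendation sets are structured field data so diffs are field-level.
    Case 2's platelet count and bleed history are supplemental values
    (required by the completeness gate, irrelevant to its neuropathic path).
    """
    case1 = PatientRecord(
        values={
            "pain_severity": D(6),
            "pain_timing": "intermittent",
            "pain_quality": "achy",
            "serum_creatinine": D("0.9"),
            "sex": "male",
            "age": D(67),
            "weight": D(84),
            "platelets": D(183000),
            "gi_bleed_history": False,
            "bowel_score": D(0),
            "opioid_regimen_adherent": True,
            "alcohol_use": False,
        },
        medications=(),
        visit_date=_dt.date(2015, 3, 2),
        session_id="CASE-0001",
    )
    case2 = PatientRecord(
        values={
            "pain_severity": D(8),
            "pain_timing": "constant",
            "pain_quality": "burning",
            "serum_creatinine": D("2.3"),
            "sex": "female",
            "age": D(53),
            "weight": D(61),
            "platelets": D(250000),
            "gi_bleed_history": False,
            "bowel_score": D(3),
            "opioid_regimen_adherent": True,
            "alcohol_use": False,
        },
        medications=(
            Medication(
                "oxycodone", "opioid", D(15), schedule="every 4 hours as needed",
                formulation="immediate-release", dose_24h=D(90),
            ),
            Medication(
                "oxycodone", "opioid", D(60), schedule="twice a day",
                formulation="extended-release", dose_24h=D(120),
            ),
            Medication(
                "sennosides", "laxative-stimulant", D(17), schedule="twice a day",
                formulation="tablet", dose_24h=D(68), tablets_per_dose=D(2),
            ),
        ),
        visit_date=_dt.date(2015, 3, 9),
        session_id="CASE-0002",
    )

    expected = {
        "case1": (
            {"category": "medication",
             "fields": {"drug": "morphine sulfate Immediate Release",
                        "dose_low": D("7.5"), "dose_high": D(15)}},
            {"category": "medication",
             "fields": {"drug": "oxycodone", "dose_low": D(5), "dose_high": D(10)}},
            {"category": "medication",
             "fields": {"drug": "hydromorphone", "dose_low": D(2), "dose_high": D(4)}},
            {"category": "medication",
             "fields": {"drug": "acetaminophen", "dose": D(1000), "times_per_day": 3,
                        "max_daily": D(3000)}},
            {"category": "medication",
             "fields": {"drug": "ibuprofen", "dose": D(400), "times_per_day": 3}},
            {"category": "medication",
             "fields": {"drug": "senna", "tablets_low": D(1), "tablets_high": D(2),
                        "max_tablets": D(4), "times_per_day": 2}},
        ),
        "case2": (
            {"category": "medication",
             "fields": {"drug": "oxycodone", "dose": D(30), "role": "rescue"}},
            {"category": "medication",
             "fields": {"drug": "oxycodone", "dose": D(120), "times_per_day": 2,
                        "daily_total": D(240)}},
            {"category": "medication",
             "fields": {"drug": "oxycodone", "dose": D(80), "times_per_day": 3,
                        "daily_total": D(240)}},
            {"category": "medication",
             "fields": {"drug": "oxycodone", "dose": D(30), "role": "rescue"}},
            {"category": "medication",
             "fields": {"drug": "fentanyl-patch", "rate": D("175.0"), "unit": "mcg/hr"}},
            {"category": "medication",
             "fields": {"drug": "oxycodone", "dose": D(30),
                        "alt_drug": "hydromorphone", "alt_dose": D(15)}},
            {"category": "medication",
             "fields": {"drug": "gabapentin", "phase1_dose": D(100), "phase2_dose": D(200),
                        "phase1_days": "1-7", "phase2_days": "8-28", "times_per_day": 2}},
            {"category": "medication",
             "fields": {"drug": "pregabalin", "phase1_dose": D(50)}},
            {"category": "medication",
             "fields": {"drug": "sennosides", "current_tablets": D(2), "max_tablets": D(4),
                        "times_per_day": 2}},
            {"category": "medication", "fields": {"times_per_day": 1}},
        ),
    }
    return case1, case2, expected


def integration_fixtures() -> tuple[PatientRecord, ...]:
    """Ten mixed-symptom cases exercising every shipped algorithm together.

    Cases are complete except the last, which lacks a serum creatinine so
    the pain algorithm returns an insufficient-data response while the
    generic algorithms still run.
    """
    cohort = generate_patient_cohort(CohortSpec(n=10, seed=20150314))
    cases = list(cohort[:9])
    cases.append(cohort[9].without("serum_creatinine"))
    return tuple(cases)
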