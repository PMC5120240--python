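# Methods

## The problem

Guideline-based symptom management in oncology (anxiety, depression,
dyspnea, fatigue, pain) can be encoded as branching clinical algorithms:
directed graphs whose interior *decision nodes* branch on one patient
variable each and whose *terminal nodes* carry care recommendations.  Real
algorithms of this kind are large — hundreds to thousands of decision-node
instances and thousands of root-to-terminal pathways — which makes two
things hard: evaluating them safely against partially collected patient
data, and demonstrating that every pathway produces the intended
recommendation.  This package implements both halves: a declarative
algorithm model with a strict validator and evaluation engine, and an
exhaustive pathway-testing framework (stack-traversal tree-spanning, STTS)
that enumerates every pathway, generates boundary-condition inputs for it,
and regression-diffs regenerated recommendations against a stored,
reviewed expectation with a 100%-agreement pass bar.

## Algorithm model

An algorithm is a rooted directed acyclic graph over a typed data
dictionary.  Branch predicates at a node must be *pairwise disjoint* and
*jointly exhaustive* over the variable's declared domain; the validator
checks this by scanning every domain value at the variable's declared
resolution (grids are small by construction: symptom scales have 5–11
points, labs a few thousand).  The payoff is at run time: a validated
algorithm can never dead-end or face two matching branches, so evaluation
needs no tie-breaking and is fully deterministic.

Complexity metrics follow per-instance counting: a clinical parameter
(e.g. a renal-function check) that appears at k distinct graph positions
contributes k decision nodes.  The pathway count is computed by dynamic
programming over the DAG and must equal the size of the exhaustive
enumeration — a cross-check the test suite performs against an independent
recursive enumerator on over a hundred seeded random DAGs.

Derived variables (creatinine clearance; the 24-hour opioid-use class)
are declared in the dictionary with `source: computed` and their raw
inputs.  Nodes branch on the derived value, which is computed on demand
and cached per evaluation; the completeness gate demands the raw
measurements.

## Completeness gating

Complete traversal of every decision node is required for correct
recommendations, so evaluation is all-or-nothing per algorithm: the
required-variable set is the union of everything any reachable predicate
or recommendation template could read, expanded from derived variables to
raw inputs.  If anything is absent the engine returns an insufficient-data
report naming exactly the missing variables and no recommendations at all.
Two deliberate consequences:

* an explicitly declined answer counts as missing (it cannot steer a
  branch);
* a record that will take the neuropathic branch still needs a platelet
  count, because the somatic branch's NSAID rule *could* have read it.
  The gate is computed from the algorithm, not from the traversal.

Gating is per algorithm: one algorithm's missing lab never blocks another
in the same visit.  (The alternative — suppressing the whole visit on any
missing variable — would be a one-line change in `evaluate_all`; the
per-algorithm rule maximises delivered guidance.)

## Clinical calculators and their calibration

Published descriptions of this class of system state categories, not
conversion arithmetic.  All numeric policy here is therefore an explicit
calibration, chosen once so the two shipped reference visits reproduce
their full printed recommendation sets exactly, and documented as such:

| parameter | value | note |
|---|---|---|
| Cockcroft-Gault | (140−age)·weight / (72·SCr), ×0.85 female | actual body weight, result rounded to 0.1 mL/min |
| renal bands | impaired < 30 mL/min ≤ normal | two groups; case 2 (27.2) lands impaired |
| equianalgesic ratios (oral) | morphine 1.0, oxycodone 1.5, hydromorphone 5.0 | patch excluded from *oral* OME |
| fentanyl patch | rate = OME ÷ 1.8, nearest 12.5 mcg/hr step | 315 OME → 175 mcg/hr |
| rescue dose | 15% of 24-h same-drug total, floored to 5 mg multiple, minimum 5 mg | 210 → 30 mg |
| SR uptitration | 24-h total × 1.15, nearest 60 mg multiple (ties up) | 210 → 241.5 → 240 → 120 BID / 80 TID |
| NSAID safety | platelets ≥ 100,000/mL and no GI-bleed history | otherwise acetaminophen only |
| acetaminophen cap | 3000 mg/day | property-tested over all rendered output |

The 60 mg snapping of the sustained-release total keeps both the
twice-daily and thrice-daily equal-total arms on 10 mg per-dose multiples;
rounding to *nearest* (not up) is what reproduces the reference titration,
and it is bounded below by one 60 mg step.  The alternative
(second-drug) rescue dose is a per-dose lookup table, not a derivation:
dispensed tablet strengths round upward, so the listed alternative
(hydromorphone 15 mg against oxycodone 30 mg) deliberately exceeds the
strict 9 mg equianalgesic equivalent, with a derive-and-round-up fallback
for doses outside the table.

All dose arithmetic uses `decimal.Decimal` end to end; rendered doses can
never show binary floating-point artefacts, and digests of serialized
output are platform-stable.

## Demo content

The pain algorithm is a deliberately faithful *fragment*, not clinically
usable guidance: severity (none {0} / mild 1–3 / moderate 4–6 / severe
7–10) → six 24-hour opioid-use classes (none, IR-only, SR-only, IR+SR,
patch-containing, non-adherent) → two renal bands → pain quality (somatic
vs neuropathic) → constipation score (0 / 1 / 2–4), with 87 decision-node
instances and 146 pathways.  The severity scale needs the explicit
zero band so the branches cover the whole 0–10 domain; a zero score routes
to a no-treatment-change terminal.  The non-adherent class comes from an
explicit patient-reported adherence flag rather than inference from the
dose history.  Two small generic symptom algorithms (anxiety, fatigue)
require only their own severity score, which is what the multi-algorithm
gating tests lean on.

Templates are plain text with `{slot}` markers and *no* logic; every slot
is filled by a named deterministic binding into the calculators.  A
binding may also report that its recommendation does not apply (NSAIDs
under bleeding risk), in which case the item is omitted entirely rather
than rendered empty.  The shipped XML content files are build products of
the content builders; the large pain document is regenerated on demand
(`cds fixtures`, `content.write_content_files`) rather than stored.

## STTS testing

Enumeration is iterative depth-first with an explicit stack of untaken
branches — follow a pathway to its end node, pop the most recent untaken
branch, continue — visiting branches in declared order so output order is
deterministic and exactly one descriptor exists per unique branch
sequence.

Boundary inputs pin each decision variable at the smallest and largest
in-branch grid values plus one interior value (categorical, boolean and
medication-class branches contribute a single representative).  Default
policy varies one variable at a time with the others at interior
representatives: full boundary coverage at linear, not combinatorial,
cost; a `full_cross` switch takes the product for small algorithms.
Constraints a pathway places on one variable through several nodes are
intersected first; an empty intersection is reported as an infeasible path
naming the conflicting nodes.  Boundaries of derived variables are
targeted in derived space — e.g. clearance exactly 30.0 mL/min — and
back-solved to raw inputs holding demographics fixed, searching the
serum-creatinine/weight grid until the engine's own rounded clearance hits
the target; unreachable targets (e.g. the nominal 3000 mL/min domain edge)
are skipped in favour of achievable near-boundary values.  Every generated
record is replayed through the engine before it is accepted.

The test database is a single-file SQLite store pairing each input with
the recommendations generated at build time, queryable by node, branch,
terminal and input value, with a flat CSV export for version-control
diffing.  Cases enter `pending` and are scored only once promoted to
`validated` — the stand-in for the expert-review step; the fixture
workflow promotes immediately.  Regression re-evaluates every validated
case and flags any difference in terminal, recommendation count, category
sequence or structured dose fields; the run passes only at 100% agreement.

## Interchange and report

Requests and responses are XML validated against shipped XSDs.  The
request schema has no slots for identifying information, and a deny-list
scan rejects documents that smuggle identifier elements (patient_name,
date_of_birth, mrn, ...) before any other processing.  The session token
is echoed verbatim; insufficient-data results carry the missing-variable
list.  Transport is out of scope — `serve_once` is the single in-process
service function.

The report model bands severities green (0–3) / yellow (4–6) / red (7–10)
on the 0–10 scales and 0–1 / 2 / 3–4 on the constipation scale — cutoffs
calibrated to the labels of the reference visits ("6 (moderate)",
"8 (severe)") and kept in one place (`report.severity_band`).  Renderings
(UTF-8 text, HTML) are pure functions of the visit history.

## Synthetic data

Generators derive independent substreams by hashing (seed, component
tags), so serialized output is reproducible across platforms and adding a
generator never perturbs another's output.  Cohorts draw symptom scores
from a band mix (default 40/35/25 green/yellow/red), labs and demographics
uniformly from their domain grids with serum creatinine skewed toward the
plausible 0.4–4.0 mg/dL range, and medication lists from a small set of
realistic 24-hour opioid exposures; a completeness probability (global or
per-variable) deletes values for gating studies.  What the cohorts do
*not* emulate: correlated symptom clusters, longitudinal disease
trajectories, or realistic epidemiology — passing tests show engine and
gating correctness on in-domain data, not clinical validity of content.
Random algorithms for oracle testing branch on small-grid raw variables
with partitioning branches by construction and occasional merge points to
exercise DAG path counting.

## Problem sizes and limitations

The shipped pain fragment yields 676 boundary cases over its 146 pathways;
a full build-and-regress cycle takes a few seconds on one CPU, and the
oracle-equivalence property is run over 100 random algorithms of depth ≤ 6
and branching ≤ 4.  Known limitations: no methadone/buprenorphine
conversion and no pediatric dosing; no cross-algorithm reconciliation of
conflicting advice; the back-solver for derived boundaries is registered
for creatinine clearance only; validator exhaustiveness checking relies on
finite declared resolutions (that is a modelling stance: values below the
resolution are not clinically distinct); and the demo content, while
calibrated to its two reference visits, is a fragment that must not be
read as clinical guidance.
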