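# symptomcds

Rule-based clinical decision support for cancer symptom management, with an
exhaustive pathway-testing framework.

Complex symptom-management guidelines (pain, anxiety, depression, dyspnea,
fatigue) can be encoded as branching clinical algorithms: rooted directed
acyclic graphs whose decision nodes branch on one patient variable each and
whose terminal nodes carry care recommendations.  Because such algorithms
reach hundreds of decision-node instances and thousands of root-to-terminal
pathways, two engineering problems dominate: running them safely against
point-of-care patient data (never emitting advice from an incomplete
traversal), and *proving* that every pathway produces the intended
recommendation.  This package provides both:

* **algorithm model** — a declarative DAG representation over a typed data
  dictionary, with a validator that enforces branch disjointness and
  exhaustiveness, acyclicity and reachability, plus complexity metrics
  (decision-node instances, pathway counts);
* **rule engine** — all-or-nothing completeness gating (missing data yields
  an insufficient-data message naming the absent variables, never partial
  recommendations) and deterministic traversal with derived quantities
  (creatinine clearance, 24-hour opioid-use class) computed on demand;
* **clinical calculators** — Cockcroft-Gault renal function
  CrCl = (140 − age) · weight / (72 · SCr) (× 0.85 for women), oral
  morphine equivalents (morphine 1.0 / oxycodone 1.5 / hydromorphone 5.0),
  rescue dosing (15% of the 24-h total, floored to 5 mg), sustained-release
  uptitration (× 1.15, snapped to equal-total BID/TID arms), transdermal
  fentanyl conversion (OME ÷ 1.8), and neuropathic/somatic/bowel adjunct
  schedules — all in exact decimal arithmetic;
* **STTS testing** — stack-traversal tree-spanning enumeration of every
  unique pathway, boundary-condition input generation (including derived
  boundaries back-solved to raw inputs), a queryable SQLite test database
  pairing each input with its expected recommendations, and a regression
  runner with a 100%-agreement pass bar;
* **interchange & report** — schema-validated XML requests/responses keyed
  by an opaque session id (no slots for identifying data, deny-list
  enforced), and a clinician report with green/yellow/red severity bands
  and cross-visit trend series;
* **synthetic fixtures** — seeded patient cohorts and random algorithms for
  oracle testing, plus two fully worked reference visits the pain content
  is calibrated against.

## Worked example

```python
from symptomcds import build_pain_demo, evaluate, worked_case_fixtures

pain = build_pain_demo()
case1, case2, _ = worked_case_fixtures()

result = evaluate(case2, pain)   # severe pain, opioid-tolerant, renal impairment
for item in result.recommendations:
    print(f"[{item.category}] {item.text}")
```

prints (first lines):

```
[medication] For symptom relief, give oxycodone at 30 mg by mouth. If pain >7 after 1 hour, suggest a palliative care consult. If pain is <6 after 1 hour, suggest you use one of the following combinations of sustained release and rescue dose opioids. Adjust to available formulations.
[medication] If oxycodone sustained release preferred: give oxycodone sustained release 120 mg by mouth twice a day.
[medication] OR 80 mg by mouth three times a day.
[medication] Give oxycodone immediate release 30 mg by mouth every 4 hours as needed.
[medication] If transdermal fentanyl patch preferred: give transdermal patch 175 mcg/hr.
```

The 30 mg rescue is 15% of the patient's actual 210 mg 24-hour oxycodone
use floored to a 5 mg step; the 240 mg/day sustained-release total
(120 mg BID ≡ 80 mg TID) is the 15% uptitration snapped to the nearest
equal-total formulation grid; 175 mcg/hr is the 315 mg/day oral-morphine
equivalent divided by 1.8.  The burning pain quality adds the gabapentin
100 mg → 200 mg schedule, and the grade-2+ constipation on sennosides adds
a titration to the 4-tablet twice-daily cap with an osmotic add-on.

Exhaustive testing of the same algorithm:

```python
from symptomcds import enumerate_paths, build_test_database, run_regression

paths = enumerate_paths(pain)          # 146 unique pathways
db = build_test_database(pain)         # 676 boundary cases, all replay-checked
diff = run_regression(pain, db)
assert diff.passed                     # 100% agreement required
```

A `cds` command line wraps the same operations (`cds validate`, `cds
metrics`, `cds run`, `cds calc`, `cds stts enumerate|build|test`,
`cds serve-once`, `cds report`, `cds fixtures`).

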