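from __future__ import annotations

import pytest

from symptomcds.content import build_generic_symptom_demo, build_pain_demo
from symptomcds.synthetic import worked_case_fixtures


@pytest.fixture(scope="session")
def pain_demo():
    return build_pain_demo()


@pytest.fixture(scope="session")
def fatigue_demo():
    return build_generic_symptom_demo("fatigue")


@pytest.fixture(scope="session")
def anxiety_demo():
    return build_generic_symptom_demo("anxiety")


@pytest.fixture(scope="session")
def worked_cases():
    """(case1, case2, expected-field-sets) reference fixtures."""
    return worked_case_fixtures()
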