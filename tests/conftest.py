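import pytest

from altoscreen.instrument import validate_respondent
from altoscreen.rules import builtin_algorithms
from altoscreen.synthetic import default_spec, generate


def make_respondent(
    rid="r1",
    diagnosis="patchy",
    q1="", q2="", q3="", q3a="", q3b="", q4="", q5="", q6="",
    **extra,
):
    """Build a validated respondent from answer strings (CSV-cell syntax)."""
    record = {
        "id": rid, "diagnosis": diagnosis,
        "q1": q1, "q2": q2, "q3": q3, "q3a": q3a, "q3b": q3b,
        "q4": q4, "q5": q5, "q6": q6,
        **extra,
    }
    return validate_respondent(record)


@pytest.fixture(scope="session")
def algorithms():
    return {a.algorithm_id: a for a in builtin_algorithms()}


@pytest.fixture(scope="session")
def transcribed(algorithms):
    return [a for a in algorithms.values() if a.is_transcribed]


@pytest.fixture(scope="session")
def pilot_spec():
    return default_spec()


@pytest.fixture(scope="session")
def default_cohort(pilot_spec):
    return generate(pilot_spec, seed_override=1)
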