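import numpy as np
import pytest

from consensim.synthetic_panel import default_behavior, default_design, default_scenarios
from consensim.trial_model import (
    AnswerOption,
    Direction,
    EvidenceMark,
    Grade,
    Scenario,
)


def make_option(oid: str, grade: str, direction: str) -> AnswerOption:
    return AnswerOption(oid, f"label {oid}", EvidenceMark(Grade(grade), Direction(direction)))


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def behavior():
    return default_behavior()


@pytest.fixture
def graded_scenario():
    """High/moderate/low pro-evidence plus a high-contra option (max points 4)."""
    return Scenario(
        "graded",
        "graded fixture",
        (
            make_option("best", "high", "pro"),
            make_option("mid", "moderate", "pro"),
            make_option("low", "low", "pro"),
            make_option("worst", "high", "contra"),
        ),
    )


@pytest.fixture
def ungraded_scenario():
    return Scenario(
        "ungraded",
        "no-evidence fixture",
        (make_option("a", "absent", "none"), make_option("b", "absent", "none")),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
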