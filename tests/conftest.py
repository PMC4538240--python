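import pytest

from bayeschoice import ElementarySituation


@pytest.fixture(scope="session")
def red_nose_counts() -> ElementarySituation:
    """The red nose village: 8 red-nosed liars, 2 plain-nosed liars,
    9 red-nosed truth-tellers, 81 plain-nosed truth-tellers."""
    return ElementarySituation(8, 2, 9, 81)


@pytest.fixture(scope="session")
def taxi_green_counts() -> ElementarySituation:
    """The reversed taxi-cab question as counts in a population of 100:
    85 green cabs of which 68 are identified as green, 15 blue cabs of
    which 3 are misidentified as green."""
    return ElementarySituation(68, 17, 3, 12)
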