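import numpy as np
import pytest

from wcstmap.task import (
    Card,
    DeckConfig,
    ExaminerConfig,
    OmniscientAgent,
    RandomAgent,
    administer,
    build_deck,
)


@pytest.fixture(scope="session")
def examiner():
    return ExaminerConfig()


@pytest.fixture(scope="session")
def default_deck():
    return build_deck(DeckConfig(seed=0))


@pytest.fixture(scope="session")
def omniscient_result(default_deck, examiner):
    return administer(OmniscientAgent(examiner), default_deck, examiner)


@pytest.fixture(scope="session")
def random_logs(examiner):
    """Consistent random-agent logs of varied lengths for likelihood tests."""
    logs = []
    for seed in range(40):
        deck = build_deck(DeckConfig(seed=seed + 100))
        res = administer(RandomAgent(seed=seed), deck, examiner)
        rng = np.random.default_rng(seed)
        length = int(rng.integers(5, 21))
        logs.append(res.trials[:length])
    return logs
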