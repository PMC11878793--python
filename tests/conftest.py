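import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def corpus():
    from molprompt.synthetic import load_fixture_corpus

    return load_fixture_corpus()


@pytest.fixture(scope="session")
def small_corpus(corpus):
    """A 40-molecule slice for fast training smoke tests."""
    return corpus[:40]


@pytest.fixture(scope="session")
def fg_table():
    from molprompt.fg_prompt import FunctionalGroupTable

    return FunctionalGroupTable.default()
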