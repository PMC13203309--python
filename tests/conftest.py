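import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ceag", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ceag")

from ceag.rule_scoring import GoldItem, NumericFact, score_all
from ceag.synth_bench import (
    BenchmarkConfig,
    generate_benchmark,
    generate_public_fixture,
)


@pytest.fixture(scope="session")
def bench():
    """Default-config synthetic benchmark: (passages, items, responses)."""
    return generate_benchmark(BenchmarkConfig())


@pytest.fixture(scope="session")
def catalog(bench):
    return {it.item_id: it for it in bench[1]}


@pytest.fixture(scope="session")
def scored(bench, catalog):
    """Scored records per regime for the default benchmark."""
    _, _, responses = bench
    return {regime: score_all(records, catalog) for regime, records in responses.items()}


@pytest.fixture(scope="session")
def public(catalog):
    return generate_public_fixture(BenchmarkConfig())


@pytest.fixture(scope="session")
def public_scored(public):
    _, items, responses = public
    cat = {it.item_id: it for it in items}
    return {regime: score_all(records, cat) for regime, records in responses.items()}


@pytest.fixture
def dosing_item():
    """A minimal hand-built gold item for slot-scorer unit tests."""
    return GoldItem(
        item_id="G1-Q1",
        doc_id="G1",
        source_date="2021-03-02",
        question="What is the velprazole dose for adults with Arlen syndrome?",
        gold_answer=(
            "For adults with Arlen syndrome, velprazole is given at "
            "500 mg every 8 hours."
        ),
        evidence_sentence=(
            "For adults with Arlen syndrome, velprazole is given at "
            "500 mg every 8 hours."
        ),
        required_qualifiers=("velprazole", "Arlen syndrome", "adults"),
        required_numbers=(
            NumericFact(500, "mg", "dose"),
            NumericFact(8, "hour", "interval"),
        ),
    )
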