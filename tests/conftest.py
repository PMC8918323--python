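import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from assistqc.consistency import UsageAnswers
from assistqc.instrument import (
    AssistResponse,
    InstrumentDefinition,
    default_instrument,
)


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def reduced_instrument(instrument):
    """Items 2 and 5 only (max total 14): small enough to enumerate exhaustively."""
    items = tuple(it for it in instrument.items if it.item_id in (2, 5))
    return InstrumentDefinition(items, {"lower": (0, 3), "moderate": (4, 14)})


def make_response(instrument, administration="screener", **ordinals):
    """Build a response from item ordinals, defaulting unmentioned items to 0."""
    sel = {}
    for it in instrument.scored_items:
        o = ordinals.get(f"item{it.item_id}", 0)
        sel[it.item_id] = it.options[o].label
    return AssistResponse(sel, administration)


@pytest.fixture(scope="session")
def use_answers(instrument):
    """Usage-probe answers that all indicate cannabis use."""
    probes = instrument.usage_probes
    return UsageAnswers(
        pattern=probes.pattern_options[2],
        times_weekday=1,
        times_weekend=2,
        hours=probes.hours_options[1],
    )


@pytest.fixture(scope="session")
def nonuse_answers(instrument):
    probes = instrument.usage_probes
    return UsageAnswers(
        pattern=probes.pattern_nonuse,
        times_weekday=0,
        times_weekend=0,
        hours=probes.hours_nonuse,
    )
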