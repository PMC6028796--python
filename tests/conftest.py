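import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=150,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mcid import CasualtyRecord, ResponderProfile


@pytest.fixture
def example_responder():
    """The worked-example responder: a 35-year-old doctor K.S. on case 1."""
    return ResponderProfile("D", "K", "S", 35, next_triage_number=1)


@pytest.fixture
def example_casualty():
    """The worked-example casualty: day 1 at 01:01, a 5-year-old boy K."""
    return CasualtyRecord(
        day_of_month=1, hour=1, minute=1, age_years=5, gender="M", name_initial="K"
    )
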