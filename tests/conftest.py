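import datetime as dt

import pytest
from hypothesis import settings

from triscreen.records import (
    EventType,
    Programme,
    ScreeningEvent,
    WomanRecord,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

REF = dt.date(2010, 12, 31)
BIRTH = dt.date(1947, 6, 15)


def make_woman(events=(), woman_id="W1", birth=BIRTH, ref=REF):
    """A woman with screens/invitations given as (programme, event_type, days_before_ref)."""
    evs = [
        ScreeningEvent(woman_id, Programme(p), EventType(t), ref - dt.timedelta(days=d))
        for p, t, d in events
    ]
    return WomanRecord(woman_id, birth, ref, events=sorted(evs, key=lambda e: e.event_date))


@pytest.fixture
def published_patterns():
    from triscreen.published import cohort_patterns

    return cohort_patterns()
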