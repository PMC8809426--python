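from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from trapid.events import Behavior, PhotoRecord
from trapid.ratings import PairRatingSet

UTC = timezone.utc
T0 = datetime(2018, 6, 1, 3, 0, tzinfo=UTC)


def photo(site="S1", minutes=0.0, **kwargs):
    defaults = dict(
        site_id=site,
        timestamp=T0 + timedelta(minutes=minutes),
        behavior_code=Behavior.NONE,
    )
    defaults.update(kwargs)
    return PhotoRecord(**defaults)


def make_ratings(event_ids, raters, verdict_of):
    """Build a complete PairRatingSet; verdict_of(pair, rater) -> 'same'/'different'."""
    ids = sorted(event_ids)
    verdicts = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            for r in raters:
                verdicts[((a, b), r)] = verdict_of((a, b), r)
    return PairRatingSet(event_ids=ids, raters=list(raters), verdicts=verdicts)


@pytest.fixture
def photo_factory():
    return photo


@pytest.fixture
def ratings_factory():
    return make_ratings
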