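from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from rarpipe.epoch_io import EpochSeries, log_transform


def make_series(
    counts,
    start: datetime = datetime(2020, 1, 1, 0, 0),
    epoch_seconds: int = 60,
    participant_id: str = "P1",
    with_log: bool = False,
    wear=None,
) -> EpochSeries:
    s = EpochSeries(
        participant_id=participant_id,
        start_time=start,
        counts=np.asarray(counts, dtype=np.int64),
        epoch_seconds=epoch_seconds,
        wear=None if wear is None else np.asarray(wear, dtype=bool),
    )
    return log_transform(s) if with_log else s


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
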