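"""Non-wear detection and valid-day / valid-participant screening.

Non-wear is flagged with the zero-count interval rule: a block of at least
``window_min`` minutes of zero counts qualifies as non-wear, allowing up to
``allowance_min`` minutes of nonzero interruptions inside the block provided
every interruption is flanked by at least ``stream_min`` minutes of
consecutive zeros on both sides. Series boundaries count as zeros for the
flanking requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np

from .epoch_io import EpochSeries
from .errors import ConfigError, DataError

__all__ = [
    "WearSummary",
    "DayRecord",
    "detect_nonwear_choi",
    "daily_wear_summary",
    "filter_valid_participants",
]


@dataclass(frozen=True)
class DayRecord:
    date: date
    wear_minutes: int
    valid_day: bool


@dataclass(frozen=True)
class WearSummary:
    participant_id: str
    days: tuple[DayRecord, ...]
    n_valid_days: int
    eligible: bool


def _minutes_to_epochs(minutes: int, epoch_seconds: int) -> int:
    return int(round(minutes * 60 / epoch_seconds))


def detect_nonwear_choi(
    series: EpochSeries,
    window_min: int = 90,
    allowance_min: int = 2,
    stream_min: int = 30,
) -> EpochSeries:
    """Return a copy of ``series`` with the wear mask populated.

    ``wear[i]`` is False exactly when epoch ``i`` lies inside some interval of
    length >= ``window_min`` that (a) starts and ends on zero-count epochs,
    (b) contains at most ``allowance_min`` minutes of nonzero counts, and
    (c) has every nonzero interruption flanked on both sides by at least
    ``stream_min`` minutes of consecutive zeros (a zero run touching the
    series edge always qualifies as a flank).
    """
    if window_min <= 0 or allowance_min < 0 or stream_min <= 0:
        raise ConfigError("non-wear parameters must be positive (allowance >= 0)")
    es = series.epoch_seconds
    window_ep = _minutes_to_epochs(window_min, es)
    allowance_ep = _minutes_to_epochs(allowance_min, es)
    stream_ep = _minutes_to_epochs(stream_min, es)

    counts = series.counts
    n = len(counts)
    wear = np.ones(n, dtype=bool)
    if n == 0:
        return series.replace(wear=wear)

    # run-length decomposition: list of (is_zero, start, stop)
    nz = counts > 0
    change = np.flatnonzero(np.diff(nz.astype(np.int8)))
    bounds = np.concatenate(([0], change + 1, [n]))
    runs = [(not nz[a], int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    # a nonzero run is an admissible interruption if both flanking zero runs
    # are long enough (or touch a series edge)
    def flank_ok(idx: int) -> bool:
        left_ok = idx > 0 and (
            runs[idx - 1][2] - runs[idx - 1][1] >= stream_ep or runs[idx - 1][1] == 0
        )
        right_ok = idx < len(runs) - 1 and (
            runs[idx + 1][2] - runs[idx + 1][1] >= stream_ep or runs[idx + 1][2] == n
        )
        return left_ok and right_ok

    # split the run sequence into segments of zero runs joined by admissible
    # bursts; no qualifying interval can cross an inadmissible burst
    segments: list[list[tuple[bool, int, int]]] = []
    current: list[tuple[bool, int, int]] = []
    for i, run in enumerate(runs):
        is_zero = run[0]
        if is_zero:
            current.append(run)
        elif flank_ok(i) and (run[2] - run[1]) <= allowance_ep:
            current.append(run)
        else:
            if current:
                segments.append(current)
            current = []
    if current:
        segments.append(current)

    for seg in segments:
        # strip leading/trailing bursts: intervals start and end on zeros
        while seg and not seg[0][0]:
            seg = seg[1:]
        while seg and not seg[-1][0]:
            seg = seg[:-1]
        if not seg:
            continue
        zero_idx = [i for i, r in enumerate(seg) if r[0]]
        # left-anchored greedy extension over zero runs: take bursts while the
        # interruption budget holds; every maximal qualifying interval is
        # produced by some anchor
        for ai, i in enumerate(zero_idx):
            start = seg[i][1]
            budget = allowance_ep
            j = i
            k = ai
            while k + 1 < len(zero_idx):
                nxt = zero_idx[k + 1]
                burst_len = sum(r[2] - r[1] for r in seg[j + 1 : nxt] if not r[0])
                if burst_len > budget:
                    break
                budget -= burst_len
                j = nxt
                k += 1
            stop = seg[j][2]
            if stop - start >= window_ep:
                wear[start:stop] = False
    return series.replace(wear=wear)


def daily_wear_summary(
    series: EpochSeries,
    min_wear_minutes: int = 600,
    min_valid_days: int = 3,
) -> WearSummary:
    """Per-calendar-date wear minutes and valid-day flags.

    A valid day has at least ``min_wear_minutes`` of wear (boundary
    inclusive); a participant is eligible with at least ``min_valid_days``
    valid days.
    """
    if series.wear is None:
        raise DataError("wear mask not populated; run detect_nonwear_choi first")
    day_idx = series.epoch_dates()
    start_date = series.start_time.date()
    records = []
    for d in np.unique(day_idx):
        sel = day_idx == d
        wear_minutes = int(round(series.wear[sel].sum() * series.epoch_seconds / 60))
        records.append(
            DayRecord(
                date=start_date + timedelta(days=int(d)),
                wear_minutes=wear_minutes,
                valid_day=wear_minutes >= min_wear_minutes,
            )
        )
    n_valid = sum(r.valid_day for r in records)
    return WearSummary(
        participant_id=series.participant_id,
        days=tuple(records),
        n_valid_days=n_valid,
        eligible=n_valid >= min_valid_days,
    )


def filter_valid_participants(
    summaries: list[WearSummary], min_valid_days: int = 3
) -> list[str]:
    """Ids of participants with enough valid days, sorted for determinism."""
    return sorted(
        s.participant_id for s in summaries if s.n_valid_days >= min_valid_days
    )
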