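"""Reading, validation, writing and time-windowing of minute-epoch activity count series.

An :class:`EpochSeries` is the pipeline's raw material: one participant's
contiguous, fixed-width epochs of non-negative integer activity counts,
carried together with an optional wear mask and cached ``ln(count + 1)``
values so every downstream stage consumes bit-identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, EmptySeriesError, FormatError

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400

_REQUIRED_COLUMNS = ("participant_id", "timestamp", "count")


@dataclass(frozen=True)
class EpochSeries:
    """Contiguous fixed-width epochs of activity counts for one participant.

    Epoch ``i`` covers ``[start_time + i*epoch_seconds, start_time + (i+1)*epoch_seconds)``.
    Timestamps are naive local clock time; series with repeated timestamps
    (daylight-saving folds) are rejected upstream.
    """

    participant_id: str
    start_time: datetime
    counts: np.ndarray
    epoch_seconds: int = 60
    wear: np.ndarray | None = None
    log_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.start_time.tzinfo is not None:
            raise DataError("start_time must be a naive local timestamp")
        if self.epoch_seconds <= 0:
            raise DataError("epoch_seconds must be positive")
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1:
            raise DataError("counts must be one-dimensional")
        if counts.size and counts.min() < 0:
            raise DataError(
                f"negative count for participant {self.participant_id!r}"
            )
        object.__setattr__(self, "counts", counts)
        for name in ("wear", "log_counts"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=bool if name == "wear" else float)
            if arr.shape != counts.shape:
                raise DataError(f"{name} length does not match counts")
            object.__setattr__(self, name, arr)

    # -- basic geometry -------------------------------------------------

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=len(self) * self.epoch_seconds)

    def epoch_starts(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(seconds=self.epoch_seconds)
        )

    def hours_of_day(self) -> np.ndarray:
        """Hour-of-day of each epoch midpoint, in [0, 24)."""
        t0 = self.start_time
        offset = (
            t0.hour * 3600 + t0.minute * 60 + t0.second + t0.microsecond / 1e6
        )
        mid = offset + (np.arange(len(self)) + 0.5) * self.epoch_seconds
        return (mid / 3600.0) % 24.0

    def epoch_dates(self) -> np.ndarray:
        """Calendar date (as days since start date) of each epoch start."""
        t0 = self.start_time
        offset = t0.hour * 3600 + t0.minute * 60 + t0.second
        sec = offset + np.arange(len(self)) * self.epoch_seconds
        return sec // SECONDS_PER_DAY

    def replace(self, **changes) -> "EpochSeries":
        return replace(self, **changes)

    def slice(self, start: int, stop: int) -> "EpochSeries":
        return replace(
            self,
            start_time=self.start_time + timedelta(seconds=start * self.epoch_seconds),
            counts=self.counts[start:stop],
            wear=None if self.wear is None else self.wear[start:stop],
            log_counts=None if self.log_counts is None else self.log_counts[start:stop],
        )


def read_epoch_csv(path: str | Path, epoch_seconds: int = 60) -> list[EpochSeries]:
    """Read an epoch CSV into one :class:`EpochSeries` per participant.

    The file must have columns ``participant_id,timestamp,count`` with
    ISO-8601 local timestamps. Rows are sorted per participant; gaps,
    duplicates and out-of-order timestamps are hard errors (no silent
    resampling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"participant_id": str})
    for col in _REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    extra = set(frame.columns) - set(_REQUIRED_COLUMNS)
    if "axis" in extra:
        logger.warning("ignoring optional 'axis' column in %s", path)
    try:
        frame["timestamp"] = pd.to_datetime(frame["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamp in {path}: {exc}") from exc
    if (frame["count"] < 0).any():
        bad = frame.loc[frame["count"] < 0].iloc[0]
        raise DataError(
            f"negative count for participant {bad['participant_id']} at {bad['timestamp']}"
        )

    out: list[EpochSeries] = []
    step = pd.Timedelta(seconds=epoch_seconds)
    for pid, grp in frame.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        ts = grp["timestamp"]
        diffs = ts.diff().iloc[1:]
        if (diffs <= pd.Timedelta(0)).any():
            first = ts.iloc[1:][diffs <= pd.Timedelta(0)].iloc[0]
            raise DataError(
                f"duplicated or non-monotone timestamp for participant {pid} at {first}"
            )
        if (diffs != step).any():
            first = ts.iloc[1:][diffs != step].iloc[0]
            raise DataError(
                f"gap in epochs for participant {pid} at {first} "
                f"(expected spacing {epoch_seconds}s)"
            )
        out.append(
            EpochSeries(
                participant_id=str(pid),
                start_time=ts.iloc[0].to_pydatetime(),
                counts=grp["count"].to_numpy(dtype=np.int64),
                epoch_seconds=epoch_seconds,
            )
        )
    return out


def write_epoch_csv(series: EpochSeries | Iterable[EpochSeries], path: str | Path) -> Path:
    """Write one or more series as an epoch CSV readable by :func:`read_epoch_csv`."""
    path = Path(path)
    if isinstance(series, EpochSeries):
        series = [series]
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": s.epoch_starts().strftime("%Y-%m-%dT%H:%M:%S"),
                    "count": s.counts,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(_REQUIRED_COLUMNS))
    out.to_csv(path, index=False)
    return path


def truncate_to_midnights(series: EpochSeries, n_days: int = 5) -> EpochSeries:
    """Clip a series to whole days: first local midnight through the midnight
    ``n_days`` later (half-open; the epoch starting at the ending midnight is
    excluded).

    A series shorter than the requested window is truncated to what is
    available with a logged warning; a series containing no midnight raises
    :class:`EmptySeriesError`.
    """
    if n_days <= 0:
        raise DataError("n_days must be positive")
    t0 = series.start_time
    offset = t0.hour * 3600 + t0.minute * 60 + t0.second + t0.microsecond / 1e6
    to_midnight = (-offset) % SECONDS_PER_DAY
    # first epoch whose start is at/after the next midnight
    start_idx = int(np.ceil(to_midnight / series.epoch_seconds))
    if start_idx >= len(series):
        raise EmptySeriesError(
            f"series for participant {series.participant_id} contains no midnight"
        )
    epochs_per_day = SECONDS_PER_DAY / series.epoch_seconds
    stop_idx = start_idx + int(round(n_days * epochs_per_day))
    if stop_idx > len(series):
        logger.warning(
            "participant %s: requested %d days from first midnight but only "
            "%.2f available; truncating to available epochs",
            series.participant_id,
            n_days,
            (len(series) - start_idx) / epochs_per_day,
        )
        stop_idx = len(series)
    return series.slice(start_idx, stop_idx)


def log_transform(series: EpochSeries) -> EpochSeries:
    """Attach ``log_counts[i] = ln(counts[i] + 1)``; counts are untouched."""
    return series.replace(log_counts=np.log1p(series.counts.astype(float)))


def concat_check(seriess: Sequence[EpochSeries]) -> None:  # pragma: no cover - debugging aid
    ids = [s.participant_id for s in seriess]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate participant ids")
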