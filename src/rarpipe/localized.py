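"""Localized (clock-time-bin) activity measures.

Complements the global cosine parameters with per-bin means and across-day
standard deviations of log activity, computed on wear epochs of valid days
only. Bins are half-open ``[a, b)`` intervals of the 24-h clock; membership
is by epoch midpoint. An optional variant re-indexes each participant's
clock so that hour 0 is their estimated rise time.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .epoch_io import EpochSeries
from .errors import ConfigError, DataError

__all__ = [
    "LocalizedMetrics",
    "bin_daily_activity",
    "summarize_bins",
    "align_to_rise_time",
    "localized_metrics_to_frame",
]


@dataclass(frozen=True)
class LocalizedMetrics:
    participant_id: str
    bin_edges: np.ndarray  # length n_bins + 1, hours
    mean_activity: np.ndarray  # per-bin across-day mean of daily bin means
    sd_activity: np.ndarray  # per-bin across-day sample SD (NaN if < 2 days)
    n_days_contributing: np.ndarray  # per-bin days with any wear in bin


def _check_bin_hours(bin_hours: float) -> int:
    n_bins = 24.0 / bin_hours
    if bin_hours <= 0 or abs(n_bins - round(n_bins)) > 1e-12:
        raise ConfigError(f"bin_hours must divide 24, got {bin_hours}")
    return int(round(n_bins))


def bin_daily_activity(
    series: EpochSeries,
    bin_hours: float = 4.0,
    valid_day_indices: set[int] | None = None,
) -> pd.DataFrame:
    """Per-day per-bin means of log activity over wear epochs.

    Returns a frame with columns ``day`` (index from series start date),
    ``bin`` (index) and ``mean`` — one row per (day, bin) cell with at least
    one wear epoch; cells fully covered by non-wear are absent (missing, not
    zero). ``valid_day_indices`` restricts to valid days when given.
    """
    n_bins = _check_bin_hours(bin_hours)
    if series.wear is None or series.log_counts is None:
        raise DataError("wear mask and log_counts must be populated")
    hours = series.hours_of_day()
    days = series.epoch_dates()
    bins = np.minimum((hours / bin_hours).astype(int), n_bins - 1)
    keep = series.wear.copy()
    if valid_day_indices is not None:
        keep &= np.isin(days, list(valid_day_indices))
    frame = pd.DataFrame(
        {"day": days[keep], "bin": bins[keep], "y": series.log_counts[keep]}
    )
    out = frame.groupby(["day", "bin"], as_index=False)["y"].mean()
    return out.rename(columns={"y": "mean"})


def summarize_bins(
    daily: pd.DataFrame,
    participant_id: str,
    bin_hours: float = 4.0,
) -> LocalizedMetrics:
    """Across-day mean and sample SD (n-1) of the daily bin means.

    A bin observed on a single day gets a mean but a missing SD; a bin never
    observed gets missing mean and SD.
    """
    n_bins = _check_bin_hours(bin_hours)
    edges = np.arange(n_bins + 1) * bin_hours
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n_days = np.zeros(n_bins, dtype=int)
    for b, grp in daily.groupby("bin"):
        vals = grp["mean"].to_numpy()
        b = int(b)
        n_days[b] = vals.size
        mean[b] = vals.mean()
        if vals.size >= 2:
            sd[b] = vals.std(ddof=1)
    return LocalizedMetrics(
        participant_id=participant_id,
        bin_edges=edges,
        mean_activity=mean,
        sd_activity=sd,
        n_days_contributing=n_days,
    )


def align_to_rise_time(
    series: EpochSeries, up_mesor: float, converged: bool = True
) -> EpochSeries:
    """Shift the clock so hour 0 is the participant's estimated rise time.

    Epoch times become ``t' = (t - up_mesor) mod 24``; day boundaries for
    binning then fall at each person's rise time ("person time"). Refused
    for participants whose rhythm fit did not converge.
    """
    if not converged:
        raise DataError("rise-time alignment refused: fit did not converge")
    shift = timedelta(hours=float(up_mesor) % 24.0)
    return series.replace(start_time=series.start_time - shift)


def localized_metrics_to_frame(metrics: list[LocalizedMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        for b in range(len(m.mean_activity)):
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "bin_start": m.bin_edges[b],
                    "bin_end": m.bin_edges[b + 1],
                    "mean_activity": m.mean_activity[b],
                    "sd_activity": m.sd_activity[b],
                    "n_days": m.n_days_contributing[b],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "bin_start",
            "bin_end",
            "mean_activity",
            "sd_activity",
            "n_days",
        ],
    )
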