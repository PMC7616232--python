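"""Data model for fixed-epoch light-exposure time series.

A wearable light logger produces an ordered sequence of (timestamp,
intensity) samples at a constant epoch (e.g. one reading per minute).
This module provides the in-memory containers shared by the whole
package:

* :class:`EpochSeries` — one channel: a regularly sampled, possibly
  gappy sequence of non-negative intensities,
* :class:`LightRecording` — a named bundle of channels sharing one time
  axis, plus a per-epoch exclusion mask,
* :class:`DailyProfile` — per-time-of-day means across days, the
  day-folding primitive behind MLiT, L5/M10 and interdaily stability.

Timestamps are timezone-naive local clock time: every metric here is
defined on clock time-of-day, and daylight-saving shifts are not
modelled. Missing values and masked epochs are treated identically
downstream — both are excluded from every sum and count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ChannelNotFoundError,
    InsufficientDataError,
    IrregularEpochError,
)

__all__ = [
    "EpochSeries",
    "LightRecording",
    "DailyProfile",
    "channel_list",
    "channel_data",
    "daily_profile",
]

DAY = pd.Timedelta(days=1)


class EpochSeries:
    """A single light channel sampled at a constant epoch.

    Parameters
    ----------
    data
        ``pandas.Series`` of float intensities indexed by a timezone-naive
        ``DatetimeIndex``. ``NaN`` marks a missing value.
    epoch_length
        Sampling interval. Required when ``data`` has a single row;
        otherwise inferred and cross-checked against the index spacing.
    allow_negative
        Raw light intensities cannot be negative, and ingestion rejects
        negative values. Transforms whose output is legitimately signed
        (log scale, zero-phase filtering) construct their results with
        ``allow_negative=True``.
    """

    __slots__ = ("_data", "_epoch")

    def __init__(
        self,
        data: pd.Series,
        epoch_length: pd.Timedelta | str | None = None,
        *,
        allow_negative: bool = False,
    ):
        if not isinstance(data, pd.Series):
            raise TypeError("data must be a pandas Series")
        if not isinstance(data.index, pd.DatetimeIndex):
            raise TypeError("data must be indexed by a DatetimeIndex")
        if data.index.tz is not None:
            raise IrregularEpochError("timestamps must be timezone-naive")
        if len(data) < 1:
            raise IrregularEpochError("series must contain at least one epoch")

        values = data.astype(float)
        if not allow_negative:
            arr = values.to_numpy()
            if np.any(arr[~np.isnan(arr)] < 0):
                raise ValueError("light intensities cannot be negative")

        if epoch_length is not None:
            epoch_length = pd.Timedelta(epoch_length)
            if epoch_length <= pd.Timedelta(0):
                raise IrregularEpochError("epoch_length must be positive")

        if len(values) > 1:
            deltas = np.diff(values.index.asi8)
            if deltas.min() <= 0:
                raise IrregularEpochError("timestamps must be strictly increasing")
            if deltas.min() != deltas.max():
                raise IrregularEpochError(
                    "timestamps must be evenly spaced at a constant epoch"
                )
            inferred = pd.Timedelta(int(deltas[0]), unit="ns")
            if epoch_length is not None and inferred != epoch_length:
                raise IrregularEpochError(
                    f"index spacing {inferred} != declared epoch {epoch_length}"
                )
            epoch_length = inferred
        elif epoch_length is None:
            raise IrregularEpochError(
                "epoch_length is required for a single-epoch series"
            )

        self._data = values
        self._epoch = epoch_length

    # -- accessors ---------------------------------------------------------

    @property
    def data(self) -> pd.Series:
        """The underlying (timestamp -> value) series. Treat as read-only."""
        return self._data

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self._data.index

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def epoch_length(self) -> pd.Timedelta:
        return self._epoch

    @property
    def epoch_seconds(self) -> float:
        return self._epoch.total_seconds()

    def __len__(self) -> int:
        return len(self._data)

    @property
    def n_valid(self) -> int:
        return int(self._data.notna().sum())

    @property
    def valid_values(self) -> np.ndarray:
        arr = self._data.to_numpy()
        return arr[~np.isnan(arr)]

    def with_values(self, values, *, allow_negative: bool = False) -> "EpochSeries":
        """New series on the same time axis with replaced values."""
        out = pd.Series(np.asarray(values, dtype=float), index=self._data.index)
        return EpochSeries(out, self._epoch, allow_negative=allow_negative)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EpochSeries(n={len(self)}, epoch={self._epoch}, "
            f"start={self.timestamps[0]}, valid={self.n_valid})"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self._epoch == other._epoch
            and self.timestamps.equals(other.timestamps)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


class LightRecording:
    """A named, multi-channel, fixed-epoch light recording.

    All channels share an identical time axis; ``mask`` is one boolean per
    epoch, ``True`` meaning the epoch is excluded from analysis (non-wear,
    covered sensor). The mask is shared by all channels.
    """

    def __init__(
        self,
        name: str,
        channels: dict[str, EpochSeries],
        mask: np.ndarray | None = None,
    ):
        if not channels:
            raise ValueError("a recording needs at least one channel")
        items = list(channels.items())
        first = items[0][1]
        for cname, series in items[1:]:
            if series.epoch_length != first.epoch_length or not series.timestamps.equals(
                first.timestamps
            ):
                raise IrregularEpochError(
                    f"channel {cname!r} does not share the recording time axis"
                )
        if mask is None:
            mask = np.zeros(len(first), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (len(first),):
                raise ValueError("mask length must equal series length")
        self.name = str(name)
        self.channels = dict(items)
        self.mask = mask

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return next(iter(self.channels.values())).timestamps

    @property
    def epoch_length(self) -> pd.Timedelta:
        return next(iter(self.channels.values())).epoch_length

    def __len__(self) -> int:
        return len(next(iter(self.channels.values())))

    def get_channel_list(self) -> list[str]:
        """Channel names in insertion order."""
        return list(self.channels.keys())

    def get_channel(self, name: str, masked: bool = False) -> EpochSeries:
        """One channel, optionally with masked epochs blanked to missing."""
        try:
            series = self.channels[name]
        except KeyError:
            raise ChannelNotFoundError(
                f"channel {name!r} not in {self.get_channel_list()}"
            ) from None
        if not masked or not self.mask.any():
            return series
        values = series.values.copy()
        values[self.mask] = np.nan
        return series.with_values(values, allow_negative=True)

    def replace(
        self,
        *,
        name: str | None = None,
        channels: dict[str, EpochSeries] | None = None,
        mask: np.ndarray | None = None,
    ) -> "LightRecording":
        return LightRecording(
            name if name is not None else self.name,
            channels if channels is not None else self.channels,
            mask if mask is not None else self.mask.copy(),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LightRecording({self.name!r}, channels={self.get_channel_list()}, "
            f"n={len(self)}, epoch={self.epoch_length}, "
            f"masked={int(self.mask.sum())})"
        )


@dataclass(frozen=True)
class DailyProfile:
    """Per-time-of-day means across days.

    ``period_means[h-1]`` is the mean of all valid observations whose
    clock time falls in period ``h`` (1-based; period ``h`` covers the
    half-open clock interval ``[(h-1)*epoch, h*epoch)``). A period with no
    valid observation is NaN.
    """

    period_means: np.ndarray
    epoch_length: pd.Timedelta
    n_days_used: int
    period_counts: np.ndarray = field(repr=False, default=None)

    @property
    def p(self) -> int:
        """Number of daily periods (1440 for minute epochs)."""
        return len(self.period_means)

    def onset_time(self, index0: int) -> pd.Timedelta:
        """Clock time-of-day at which 0-based period ``index0`` starts."""
        return index0 * self.epoch_length


def channel_list(recording: LightRecording) -> list[str]:
    """Names of the light channels in a recording, in insertion order."""
    return recording.get_channel_list()


def channel_data(
    recording: LightRecording, name: str, masked: bool = False
) -> EpochSeries:
    """One channel of a recording; ``masked=True`` blanks masked epochs."""
    return recording.get_channel(name, masked=masked)


def periods_per_day(series: EpochSeries) -> int:
    """How many epochs fit in 24 h; error if the epoch does not divide a day."""
    day_ns = DAY.value
    epoch_ns = series.epoch_length.value
    if day_ns % epoch_ns != 0:
        raise IrregularEpochError(
            f"epoch {series.epoch_length} does not divide 24 h"
        )
    return day_ns // epoch_ns


def fold_indices(series: EpochSeries, period: pd.Timedelta) -> np.ndarray:
    """0-based folding index of every epoch for a given folding period.

    The fold is anchored at the midnight preceding the first timestamp, so
    for a 24 h period the index is exactly the time-of-day period index.
    The epoch must divide the folding period.
    """
    period = pd.Timedelta(period)
    epoch_ns = series.epoch_length.value
    if period.value % epoch_ns != 0:
        raise IrregularEpochError(
            f"epoch {series.epoch_length} does not divide folding period {period}"
        )
    k = period.value // epoch_ns
    anchor = series.timestamps[0].normalize()
    offsets = (series.timestamps.asi8 - anchor.value) // epoch_ns
    return (offsets % k).astype(np.intp)


def trim_whole_days(series: EpochSeries) -> tuple[EpochSeries, int]:
    """Restrict a series to complete midnight-to-midnight days.

    Returns the trimmed series and the number of whole days kept. Raises
    :class:`InsufficientDataError` if the recording contains no whole day.
    """
    p = periods_per_day(series)
    ts = series.timestamps
    first_midnight = ts[0].normalize()
    if ts[0] != first_midnight:
        first_midnight += DAY
    start_pos = int(ts.searchsorted(first_midnight))
    n_days = (len(series) - start_pos) // p
    if n_days < 1:
        raise InsufficientDataError("recording contains no whole day")
    data = series.data.iloc[start_pos : start_pos + n_days * p]
    return EpochSeries(data, series.epoch_length, allow_negative=True), n_days


def daily_profile(series: EpochSeries, whole_days_only: bool = False) -> DailyProfile:
    """Fold a series on clock time-of-day and average across days.

    Parameters
    ----------
    series
        Any series whose epoch divides 24 h.
    whole_days_only
        Drop leading/trailing partial days before folding. The default
        keeps all data: partial days simply contribute fewer observations
        to the affected periods.
    """
    if whole_days_only:
        series, n_days = trim_whole_days(series)
    else:
        n_days = len(np.unique(series.timestamps.normalize().asi8))
    p = periods_per_day(series)
    idx = fold_indices(series, DAY)
    values = series.values
    valid = ~np.isnan(values)
    sums = np.bincount(idx[valid], weights=values[valid], minlength=p)
    counts = np.bincount(idx[valid], minlength=p)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DailyProfile(
        period_means=means,
        epoch_length=series.epoch_length,
        n_days_used=int(n_days),
        period_counts=counts,
    )
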