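"""Light-exposure metrics.

All metrics operate on an :class:`~luxlog.core.EpochSeries` (apply the
recording mask first via ``channel_data(..., masked=True)`` if desired)
and follow one shared convention: missing values are excluded from every
sum and count, and "above threshold" means strictly ``value > C``.

Implemented metrics
-------------------
* summary statistics over the whole recording or user windows,
* light exposure level — the mean intensity, optionally restricted to
  supra-threshold epochs,
* TAT(C) — time above threshold: the total duration with intensity
  above ``C``,
* MLiT(C) — mean light timing above threshold (Reid et al.): the
  indicator-weighted mean daily-period index

      MLiT(C) = sum_{j,k} j * I_jk(C) / sum_{j,k} I_jk(C)

  where ``I_jk`` is 1 iff the intensity in daily period ``j`` of day
  ``k`` exceeds ``C``; ``j`` runs over the ``m`` periods of a day (1440
  for minute epochs) and ``k`` over the ``n`` days,
* L5 / M10 — onset and mean of the 5-h window of least and the 10-h
  window of maximal exposure, computed on the average daily profile
  with circular (wrap-around) windows,
* IS — interdaily stability, the variance of the 24-h average profile
  over the total variance:

      IS = n * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2)

  which equals the 24-h chi-square periodogram value normalised by the
  number of periods ``n`` (:func:`is_at_period` generalises the folding
  period),
* IV — intradaily variability, the mean squared first difference over
  the variance:

      IV = n * sum_i (x_{i+1} - x_i)^2 / ((n-1) * sum_i (x_i - xbar)^2)

IS is 1 for a perfectly repeated daily pattern and tends to 1/d for
d days of independent noise; IV tends to 2 for white noise and to 0 for
a slowly varying signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DAY,
    DailyProfile,
    EpochSeries,
    LightRecording,
    daily_profile,
    periods_per_day,
    trim_whole_days,
)
from .errors import (
    EmptySelectionError,
    InsufficientDataError,
    IrregularEpochError,
    LuxlogError,
    ParameterError,
    UndefinedMetricError,
)
from .preprocess import resample

__all__ = [
    "MLiTResult",
    "WindowResult",
    "MetricTable",
    "MetricSpec",
    "summary_statistics",
    "light_exposure_level",
    "tat",
    "tat_per_window",
    "mlit",
    "l5m10",
    "extreme_window",
    "interdaily_stability",
    "intradaily_variability",
    "is_at_period",
    "compute_metric_table",
    "METRIC_REGISTRY",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class MLiTResult:
    """Mean light timing above a threshold.

    ``index`` is the fractional 1-based daily-period index defined by the
    MLiT equation; ``clock_time`` converts it to clock time using the
    epoch-start convention: period ``j`` covers ``[(j-1)*epoch, j*epoch)``,
    so ``clock_time = (index - 1) * epoch`` after midnight. When no epoch
    exceeds the threshold the index is NaN and ``clock_time`` is None.
    """

    index: float
    clock_time: pd.Timedelta | None
    m: int
    n: int
    exceedance_count: int


@dataclass(frozen=True)
class WindowResult:
    """One extreme window (L5 or M10) on the daily profile."""

    onset: pd.Timedelta  # clock time-of-day of the window's first period
    mean_value: float
    window_length: pd.Timedelta

    @property
    def onset_hours(self) -> float:
        return self.onset.total_seconds() / 3600.0


class MetricTable:
    """Rectangular table: rows = recordings, columns = named metrics."""

    def __init__(self, frame: pd.DataFrame, errors=None):
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ParameterError("metric table keys must be unique")
        self.frame = frame
        self.errors: list[tuple[str, str, Exception]] = list(errors or [])

    @classmethod
    def from_rows(cls, rows: dict[str, pd.Series], errors=None) -> "MetricTable":
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "name"
        return cls(frame, errors=errors)

    def to_csv(self, path) -> None:
        from .io_text import write_summary

        write_summary(self, path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MetricTable({self.frame.shape[0]}x{self.frame.shape[1]})"


# ---------------------------------------------------------------------------
# aggregated statistics


def _window_slice(series: EpochSeries, start, stop) -> np.ndarray:
    ts = series.timestamps
    return np.asarray((ts >= pd.Timestamp(start)) & (ts < pd.Timestamp(stop)))


def summary_statistics(
    series: EpochSeries,
    windows=None,
    percentiles: tuple[float, ...] = (25.0, 75.0),
) -> pd.Series:
    """Mean, median, SD, min, max and percentiles over valid values.

    With ``windows`` (a list of half-open ``(start, stop)`` pairs) the
    statistics are computed per window and the keys are suffixed with the
    window start; a window with no valid data yields missing cells.
    """
    if series.n_valid == 0 and windows is None:
        raise EmptySelectionError("series has no valid values")

    def stats_of(values: np.ndarray) -> dict[str, float]:
        values = values[~np.isnan(values)]
        if values.size == 0:
            keys = ["mean", "median", "std", "min", "max"] + [
                f"p{q:g}" for q in percentiles
            ]
            return {k: np.nan for k in keys}
        out = {
            "mean": float(np.mean(values)),
            "median": float(np.median(values)),
            "std": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
            "min": float(np.min(values)),
            "max": float(np.max(values)),
        }
        for q in percentiles:
            out[f"p{q:g}"] = float(np.percentile(values, q))
        return out

    if windows is None:
        return pd.Series(stats_of(series.values))
    cells = {}
    for start, stop in windows:
        sel = _window_slice(series, start, stop)
        label = pd.Timestamp(start).isoformat()
        for key, val in stats_of(series.values[sel]).items():
            cells[f"{key}@{label}"] = val
    return pd.Series(cells)


def light_exposure_level(series: EpochSeries, C: float | None = None) -> float:
    """Mean intensity, optionally restricted to values strictly above ``C``.

    Returns NaN when no valid value exceeds the threshold.
    """
    values = series.valid_values
    if C is not None:
        values = values[values > C]
    if values.size == 0:
        return float("nan")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# threshold-based timing metrics


_TAT_FORMATS = ("minute", "timedelta", "count")


def tat(series: EpochSeries, C: float, output_format: str = "minute"):
    """Time above threshold: total duration with intensity above ``C``.

    Equals ``epoch_length x (number of valid epochs with value > C)``,
    expressed in minutes (float), as a ``Timedelta``, or as the raw epoch
    count.
    """
    if output_format not in _TAT_FORMATS:
        raise ParameterError(
            f"output_format must be one of {_TAT_FORMATS}, got {output_format!r}"
        )
    values = series.valid_values
    count = int(np.sum(values > C))
    if output_format == "count":
        return count
    duration = count * series.epoch_length
    if output_format == "timedelta":
        return duration
    return duration.total_seconds() / 60.0


def tat_per_window(
    series: EpochSeries, C: float, windows, output_format: str = "minute"
) -> pd.Series:
    """TAT restricted to each half-open ``(start, stop)`` window."""
    cells = {}
    for start, stop in windows:
        sel = _window_slice(series, start, stop)
        sub = series.values[sel]
        sub = sub[~np.isnan(sub)]
        count = int(np.sum(sub > C))
        if output_format == "count":
            val = count
        elif output_format == "timedelta":
            val = count * series.epoch_length
        elif output_format == "minute":
            val = (count * series.epoch_length).total_seconds() / 60.0
        else:
            raise ParameterError(f"unknown output_format {output_format!r}")
        cells[pd.Timestamp(start).isoformat()] = val
    return pd.Series(cells)


def mlit(series: EpochSeries, C: float, whole_days_only: bool = False) -> MLiTResult:
    """Mean light timing above threshold ``C``.

    Evaluates the indicator-weighted mean daily-period index (see module
    docstring). Missing epochs contribute 0 to both sums. ``m`` is the
    number of daily periods (1440 for minute data) and ``n`` the number
    of days spanned. With ``whole_days_only`` leading/trailing partial
    days are dropped first.
    """
    if whole_days_only:
        series, n_days = trim_whole_days(series)
    else:
        n_days = len(np.unique(series.timestamps.normalize().asi8))
    m = periods_per_day(series)
    # 1-based daily period index j of every epoch
    anchor = series.timestamps[0].normalize()
    offsets = (series.timestamps.asi8 - anchor.value) // series.epoch_length.value
    j = (offsets % m) + 1
    values = series.values
    with np.errstate(invalid="ignore"):
        above = (values > C) & ~np.isnan(values)
    denominator = int(above.sum())
    if denominator == 0:
        return MLiTResult(
            index=float("nan"), clock_time=None, m=m, n=n_days, exceedance_count=0
        )
    index = float(j[above].sum()) / denominator
    clock = pd.Timedelta((index - 1.0) * series.epoch_length.value, unit="ns")
    return MLiTResult(
        index=index, clock_time=clock, m=m, n=n_days, exceedance_count=denominator
    )


# ---------------------------------------------------------------------------
# L5 / M10


def extreme_window(
    profile: DailyProfile, window_length, kind: str
) -> WindowResult:
    """Find the circular window of the daily profile with extreme mean.

    ``kind`` is "min" (L5-style) or "max" (M10-style). Candidate onsets
    are every profile period; windows wrap past midnight. A candidate
    containing a missing period is excluded; if every candidate is
    excluded an :class:`InsufficientDataError` is raised. Ties go to the
    earliest onset in [00:00, 24:00).
    """
    if kind not in ("min", "max"):
        raise ParameterError("kind must be 'min' or 'max'")
    window_length = pd.Timedelta(window_length)
    epoch_ns = profile.epoch_length.value
    if window_length.value % epoch_ns != 0:
        raise ParameterError(
            f"window {window_length} is not a multiple of epoch {profile.epoch_length}"
        )
    w = window_length.value // epoch_ns
    p = profile.p
    if not 0 < w <= p:
        raise ParameterError("window must be positive and at most one day")
    x = profile.period_means
    doubled = np.concatenate([x, x[: w - 1]]) if w > 1 else x
    # rolling mean over every circular onset; NaN where window has a gap
    means = np.full(p, np.nan)
    csum = np.nancumsum(np.concatenate([[0.0], doubled]))
    nan_flags = np.isnan(doubled).astype(int)
    ncum = np.concatenate([[0], np.cumsum(nan_flags)])
    for onset in range(p):
        if ncum[onset + w] - ncum[onset] == 0:
            means[onset] = (csum[onset + w] - csum[onset]) / w
    if np.isnan(means).all():
        raise InsufficientDataError(
            "every candidate window contains a missing profile period"
        )
    onset = int(np.nanargmin(means) if kind == "min" else np.nanargmax(means))
    return WindowResult(
        onset=profile.onset_time(onset),
        mean_value=float(means[onset]),
        window_length=window_length,
    )


def l5m10(
    series: EpochSeries, whole_days_only: bool = False
) -> tuple[WindowResult, WindowResult]:
    """L5 and M10: least-exposed 5-h and most-exposed 10-h daily windows.

    Computed on the averaged daily profile with circular windows, so the
    result is a property of the typical day rather than of any single
    day. Returns ``(L5, M10)``.
    """
    profile = daily_profile(series, whole_days_only=whole_days_only)
    l5 = extreme_window(profile, pd.Timedelta(hours=5), "min")
    m10 = extreme_window(profile, pd.Timedelta(hours=10), "max")
    return l5, m10


# ---------------------------------------------------------------------------
# nonparametric rhythm metrics (IS / IV)


def _folded_stability(series: EpochSeries, fold_period: pd.Timedelta) -> float:
    """IS formula with an arbitrary folding period (chi-square periodogram
    value at that period, normalised by the number of valid samples)."""
    from .core import fold_indices  # local import keeps core free of metrics

    fold_period = pd.Timedelta(fold_period)
    epoch_ns = series.epoch_length.value
    if fold_period.value % epoch_ns != 0:
        raise IrregularEpochError(
            f"epoch {series.epoch_length} does not divide period {fold_period}"
        )
    p = fold_period.value // epoch_ns
    idx = fold_indices(series, fold_period)
    values = series.values
    valid = ~np.isnan(values)
    x = values[valid]
    if x.size < 2:
        raise InsufficientDataError("need at least 2 valid samples for IS")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("IS undefined for a constant series (0/0)")
    grand = x.mean()
    sums = np.bincount(idx[valid], weights=x, minlength=p)
    counts = np.bincount(idx[valid], minlength=p)
    have = counts > 0
    group_means = sums[have] / counts[have]
    numerator = np.mean((group_means - grand) ** 2)
    denominator = np.mean((x - grand) ** 2)
    return float(numerator / denominator)


def interdaily_stability(series: EpochSeries, freq=None) -> float:
    """Interdaily stability: how reproducible the 24-h pattern is across days.

    IS is the variance of the average daily profile over the total
    variance; 1 for a perfectly repeated pattern, ~1/d for d days of
    independent noise. ``freq`` optionally resamples (mean aggregation)
    to a coarser epoch first — IS is frequency-sensitive, so the caller
    controls the evaluation epoch explicitly (hourly is the traditional
    choice).
    """
    if freq is not None:
        series = resample(series, freq, "mean")
    return _folded_stability(series, DAY)


def is_at_period(series: EpochSeries, test_period) -> float:
    """The IS formula folded at an arbitrary test period.

    ``is_at_period(series, '24h')`` is interdaily stability; scanning
    ``test_period`` turns this into a normalised chi-square periodogram
    whose maximum sits near the true rhythm period.
    """
    return _folded_stability(series, pd.Timedelta(test_period))


def intradaily_variability(series: EpochSeries, freq=None) -> float:
    """Intradaily variability: fragmentation of the signal within the day.

    Ratio of the mean squared first difference to the variance; ~2 for
    white noise, near 0 for a smooth diurnal profile. Differences are
    taken only over pairs of adjacent epochs where both values are valid,
    and the pair count replaces (n-1) in the normalisation.
    """
    if freq is not None:
        series = resample(series, freq, "mean")
    values = series.values
    valid = ~np.isnan(values)
    x = values[valid]
    if x.size < 2:
        raise InsufficientDataError("need at least 2 valid samples for IV")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("IV undefined for a constant series (0/0)")
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        raise InsufficientDataError("no adjacent valid pairs for IV")
    diffs = values[1:][pair] - values[:-1][pair]
    msd = float(np.mean(diffs**2))
    var = float(np.mean((x - x.mean()) ** 2))
    return msd / var


# ---------------------------------------------------------------------------
# batch metric tables


@dataclass(frozen=True)
class MetricSpec:
    """One requested metric column: registry name, parameters, column name."""

    metric: str
    params: dict
    name: str | None = None

    @property
    def column(self) -> str:
        if self.name:
            return self.name
        if "C" in self.params:
            return f"{self.metric}_{self.params['C']:g}"
        return self.metric


def _scalar_mlit(series, **kw):
    return mlit(series, **kw).index


def _scalar_tat(series, **kw):
    value = tat(series, **kw)
    if isinstance(value, pd.Timedelta):
        return value.total_seconds() / 60.0
    return float(value)


def _scalar_l5(series, field, **kw):
    l5, _ = l5m10(series, **kw)
    return l5.mean_value if field == "mean" else l5.onset_hours


def _scalar_m10(series, field, **kw):
    _, m10 = l5m10(series, **kw)
    return m10.mean_value if field == "mean" else m10.onset_hours


METRIC_REGISTRY = {
    "mean": lambda s: light_exposure_level(s),
    "exposure_level": light_exposure_level,
    "tat": _scalar_tat,
    "mlit": _scalar_mlit,
    "is": interdaily_stability,
    "iv": intradaily_variability,
    "is_at_period": lambda s, test_period: is_at_period(s, test_period),
    "l5_mean": lambda s, **kw: _scalar_l5(s, "mean", **kw),
    "l5_onset": lambda s, **kw: _scalar_l5(s, "onset", **kw),
    "m10_mean": lambda s, **kw: _scalar_m10(s, "mean", **kw),
    "m10_onset": lambda s, **kw: _scalar_m10(s, "onset", **kw),
    "median": lambda s: float(np.nanmedian(s.values)) if s.n_valid else float("nan"),
    "std": lambda s: float(np.nanstd(s.values, ddof=1)) if s.n_valid > 1 else 0.0,
}


def compute_metric_table(
    recordings: list[LightRecording],
    channel: str,
    spec: list,
    masked: bool = True,
) -> MetricTable:
    """One row per recording, one column per requested metric.

    ``spec`` entries may be :class:`MetricSpec` objects or
    ``(metric, params)`` / ``(metric, params, name)`` tuples. A metric
    failing on one recording (e.g. IS undefined on a constant series)
    leaves a missing cell and an entry in ``table.errors``; batch runs
    never abort on a single bad recording.
    """
    if not recordings:
        raise ParameterError("need at least one recording")
    if not spec:
        raise ParameterError("need at least one metric")
    specs = []
    for entry in spec:
        if isinstance(entry, MetricSpec):
            specs.append(entry)
        else:
            specs.append(MetricSpec(*entry))
    for ms in specs:
        if ms.metric not in METRIC_REGISTRY:
            raise ParameterError(
                f"unknown metric {ms.metric!r}; known: {sorted(METRIC_REGISTRY)}"
            )
    rows, errors = {}, []
    for rec in recordings:
        series = rec.get_channel(channel, masked=masked)
        cells = {}
        for ms in specs:
            try:
                cells[ms.column] = float(METRIC_REGISTRY[ms.metric](series, **ms.params))
            except LuxlogError as exc:
                cells[ms.column] = float("nan")
                errors.append((rec.name, ms.column, exc))
        rows[rec.name] = pd.Series(cells)
    return MetricTable.from_rows(rows, errors=errors)
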