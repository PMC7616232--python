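"""Data conditioning for light recordings.

Masking, window truncation, block resampling, zero-phase Butterworth
filtering, log transform, thresholding and binarization. These steps sit
between raw ingestion and metric computation; each returns a new object
and never mutates its input.

Threshold comparisons are STRICT everywhere in this package: a value
counts as "above threshold" iff ``value > C``. The same rule is used by
:func:`threshold_filter`, :func:`binarize` and every threshold-based
metric, so identities such as TAT = epoch x sum(binarize) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import EpochSeries, LightRecording
from .errors import (
    DomainError,
    EmptySelectionError,
    InvalidFilterError,
    MissingDataError,
    ParameterError,
    ResampleIncompatibilityError,
)
from .io_text import MaskSpec

__all__ = [
    "AGGREGATIONS",
    "FilterSpec",
    "apply_mask",
    "truncate",
    "resample",
    "butterworth_filter",
    "log_transform",
    "threshold_filter",
    "binarize",
]

#: Closed set of block-aggregation functions for :func:`resample`.
AGGREGATIONS = ("sum", "mean", "median", "min", "max")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification.

    Cutoffs are given in cycles per day — the natural unit for circadian
    data (1 cpd is the diurnal component) — and converted internally
    using the series' epoch length.
    """

    kind: str  # lowpass | highpass | bandpass | bandstop
    cutoffs_cpd: tuple[float, ...]
    order: int = 3

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass", "bandpass", "bandstop"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        n_expected = 2 if self.kind in ("bandpass", "bandstop") else 1
        if len(self.cutoffs_cpd) != n_expected:
            raise ParameterError(
                f"{self.kind} requires exactly {n_expected} cutoff(s)"
            )
        if any(c <= 0 for c in self.cutoffs_cpd):
            raise InvalidFilterError("cutoffs must be positive")
        if n_expected == 2 and not self.cutoffs_cpd[0] < self.cutoffs_cpd[1]:
            raise InvalidFilterError("band cutoffs must be strictly increasing")
        if self.order < 1:
            raise ParameterError("filter order must be a positive integer")


def apply_mask(recording: LightRecording, spec: MaskSpec) -> LightRecording:
    """Mark every epoch falling inside the union of mask intervals.

    Masking is cumulative: epochs already masked stay masked (union
    semantics), so applying specs in any order, or twice, gives the same
    result. Intervals outside the recording are silently ignored; channel
    values are untouched.
    """
    mask = recording.mask.copy()
    ts = recording.timestamps.asi8
    for start, stop in spec.intervals:
        start_ns = pd.Timestamp(start).value
        stop_ns = pd.Timestamp(stop).value
        mask |= (ts >= start_ns) & (ts < stop_ns)
    return recording.replace(mask=mask)


def truncate(
    recording: LightRecording,
    start: pd.Timestamp | str | None = None,
    period: pd.Timedelta | str | None = None,
) -> LightRecording:
    """Restrict a recording to the half-open window [start, start+period).

    ``start`` defaults to the first timestamp; ``period`` to the rest of
    the recording. The half-open convention makes ``period='6D'`` on
    minute data yield exactly 8640 epochs.
    """
    ts = recording.timestamps
    start = ts[0] if start is None else pd.Timestamp(start)
    if period is None:
        keep = ts >= start
    else:
        period = pd.Timedelta(period)
        keep = (ts >= start) & (ts < start + period)
    if not keep.any():
        raise EmptySelectionError(
            f"window [{start}, +{period}) does not intersect the recording"
        )
    sel = np.asarray(keep)
    channels = {
        name: EpochSeries(
            series.data[sel], recording.epoch_length, allow_negative=True
        )
        for name, series in recording.channels.items()
    }
    return LightRecording(recording.name, channels, recording.mask[sel])


def resample(series: EpochSeries, new_epoch, agg: str = "mean") -> EpochSeries:
    """Aggregate consecutive blocks of epochs into a coarser epoch.

    ``new_epoch`` must be a positive integer multiple of the current
    epoch. Blocks are non-overlapping, left-labelled (block timestamp =
    block start) and aggregated over non-missing values only; a block
    with no valid value becomes missing.
    """
    if agg not in AGGREGATIONS:
        raise ParameterError(f"agg must be one of {AGGREGATIONS}, got {agg!r}")
    new_epoch = pd.Timedelta(new_epoch)
    old_ns = series.epoch_length.value
    if new_epoch.value <= 0 or new_epoch.value % old_ns != 0:
        raise ResampleIncompatibilityError(
            f"new epoch {new_epoch} is not an integer multiple of {series.epoch_length}"
        )
    if new_epoch.value == old_ns:
        return series
    resampler = series.data.resample(new_epoch, origin=series.timestamps[0])
    if agg == "sum":
        out = resampler.sum(min_count=1)  # all-NaN block -> NaN, not 0
    else:
        out = getattr(resampler, agg)()
    return EpochSeries(out, new_epoch, allow_negative=True)


def butterworth_filter(series: EpochSeries, spec: FilterSpec) -> EpochSeries:
    """Zero-phase (forward-backward) Butterworth filter.

    The input must be gap-free: the caller decides how to handle missing
    data before filtering. The effective amplitude response is the squared
    magnitude of the single-pass Butterworth response (filtfilt applies it
    twice). Output is not clipped and may be negative.
    """
    values = series.values
    if np.isnan(values).any():
        raise MissingDataError(
            "butterworth_filter requires gap-free data; mask or fill gaps first"
        )
    fs = 1.0 / series.epoch_seconds  # Hz
    nyquist = fs / 2.0
    cutoffs_hz = np.asarray(spec.cutoffs_cpd, dtype=float) / 86400.0
    if np.any(cutoffs_hz >= nyquist):
        raise InvalidFilterError(
            f"cutoff(s) {spec.cutoffs_cpd} cpd at or above Nyquist "
            f"({nyquist * 86400:.3g} cpd for epoch {series.epoch_length})"
        )
    wn = cutoffs_hz if len(cutoffs_hz) > 1 else cutoffs_hz[0]
    sos = signal.butter(spec.order, wn, btype=spec.kind, fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, values)
    return series.with_values(filtered, allow_negative=True)


def log_transform(series: EpochSeries, offset: float = 1.0) -> EpochSeries:
    """Elementwise ``log10(value + offset)``; missing stays missing.

    The conventional offset of 1 maps darkness (0 lx) to 0 and keeps the
    transform defined at night. Any value with ``value + offset <= 0``
    is a domain error.
    """
    values = series.values
    shifted = values + offset
    bad = shifted[~np.isnan(shifted)] <= 0
    if bad.any():
        raise DomainError(
            f"{int(bad.sum())} value(s) have value + offset <= 0; "
            "log10 undefined"
        )
    with np.errstate(invalid="ignore"):
        out = np.log10(shifted)
    return series.with_values(out, allow_negative=True)


def threshold_filter(series: EpochSeries, C: float) -> EpochSeries:
    """Discard (set to missing) every value not strictly above ``C``."""
    values = series.values.copy()
    with np.errstate(invalid="ignore"):
        values[values <= C] = np.nan
    return series.with_values(values, allow_negative=True)


def binarize(series: EpochSeries, C: float) -> EpochSeries:
    """Replace values strictly above ``C`` with 1, others with 0.

    Missing values stay missing.
    """
    values = series.values
    with np.errstate(invalid="ignore"):
        out = (values > C).astype(float)
    out[np.isnan(values)] = np.nan
    return series.with_values(out)
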