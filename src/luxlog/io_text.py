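"""Text-based I/O: device CSV exports, mask files, summary tables.

Light loggers from different vendors export very different CSV flavours
(delimiters, decimal marks, timestamp formats, metadata preambles).
Rather than one parser per device, everything funnels through a single
:class:`CsvDialect` describing the export, which keeps the package
device-agnostic: any logger whose data can be exported to delimited text
is supported.

Mask intervals live in a small JSON document so they can be edited by
hand and kept next to the data::

    {"masks": [{"start": "2016-09-07T22:00:00", "stop": "2016-09-08T07:00:00"}]}

Intervals are half-open ``[start, stop)`` and may overlap (union
semantics).
"""

from __future__ import annotations

import glob as _glob
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochSeries, LightRecording
from .errors import (
    EmptySelectionError,
    InvalidIntervalError,
    ParameterError,
    ParseError,
)

__all__ = [
    "CsvDialect",
    "MaskSpec",
    "read_recording",
    "read_batch",
    "read_mask_file",
    "write_summary",
]


@dataclass(frozen=True)
class CsvDialect:
    """How to interpret a device's delimited-text export.

    ``decimal_mark`` subsumes locale handling (e.g. German exports use
    ','); ``skip_prefix`` drops metadata/comment lines anywhere in the
    file and ``skip_rows`` additionally drops a fixed-size preamble.
    """

    channel_columns: tuple[str, ...]
    timestamp_column: str = "timestamp"
    delimiter: str = ","
    decimal_mark: str = "."
    timestamp_format: str | None = None  # None -> ISO-8601 / auto
    skip_prefix: str = "#"
    skip_rows: int = 0
    missing_tokens: tuple[str, ...] = ("", "NaN", "NA")

    def __post_init__(self):
        if isinstance(self.channel_columns, str):
            object.__setattr__(self, "channel_columns", (self.channel_columns,))
        else:
            object.__setattr__(self, "channel_columns", tuple(self.channel_columns))
        object.__setattr__(self, "missing_tokens", tuple(self.missing_tokens))
        if not self.channel_columns:
            raise ParameterError("dialect needs at least one channel column")
        if self.timestamp_column in self.channel_columns:
            raise ParameterError("timestamp column cannot also be a channel")
        if self.delimiter == self.decimal_mark:
            raise ParameterError("delimiter and decimal mark must differ")
        if self.decimal_mark not in (".", ","):
            raise ParameterError("decimal mark must be '.' or ','")


@dataclass(frozen=True)
class MaskSpec:
    """A list of half-open [start, stop) intervals to exclude from analysis."""

    intervals: tuple[tuple[pd.Timestamp, pd.Timestamp], ...] = ()

    def __post_init__(self):
        norm = []
        for start, stop in self.intervals:
            start, stop = pd.Timestamp(start), pd.Timestamp(stop)
            if start >= stop:
                raise InvalidIntervalError(
                    f"mask interval must have start < stop, got [{start}, {stop})"
                )
            norm.append((start, stop))
        object.__setattr__(self, "intervals", tuple(norm))

    def __len__(self) -> int:
        return len(self.intervals)


def _read_lines(path: Path, dialect: CsvDialect) -> tuple[str, list[int]]:
    """Strip preamble/comment lines; return CSV text and original line numbers."""
    kept, line_numbers = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= dialect.skip_rows:
                continue
            if dialect.skip_prefix and line.startswith(dialect.skip_prefix):
                continue
            if not line.strip():
                continue
            kept.append(line)
            line_numbers.append(lineno)
    if not kept:
        raise ParseError("file contains no data rows", path=path)
    return "".join(kept), line_numbers


def read_recording(
    path,
    dialect: CsvDialect,
    start_time=None,
    period=None,
    name: str | None = None,
) -> LightRecording:
    """Read one device CSV export into a :class:`LightRecording`.

    The recording is restricted to the half-open window
    ``[start_time, start_time + period)`` (``start_time`` defaults to the
    first timestamp; ``period=None`` keeps everything). The epoch is
    inferred from consecutive timestamps and must be constant; the mask
    is initialised all-false.
    """
    path = Path(path)
    text, line_numbers = _read_lines(path, dialect)
    try:
        frame = pd.read_csv(
            io.StringIO(text),
            sep=dialect.delimiter,
            dtype=str,
            keep_default_na=False,
        )
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"cannot parse CSV: {exc}", path=path) from exc

    missing_cols = [
        c
        for c in (dialect.timestamp_column, *dialect.channel_columns)
        if c not in frame.columns
    ]
    if missing_cols:
        raise ParseError(
            f"missing column(s) {missing_cols}; found {list(frame.columns)}",
            path=path,
            line=line_numbers[0],
        )
    # line_numbers[0] is the header line
    data_lines = line_numbers[1 : len(frame) + 1]

    raw_ts = frame[dialect.timestamp_column].str.strip()
    timestamps = pd.to_datetime(
        raw_ts, format=dialect.timestamp_format, errors="coerce"
    )
    bad = timestamps.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"unparsable timestamp {raw_ts.iloc[i]!r}",
            path=path,
            line=data_lines[i],
        )

    channels: dict[str, EpochSeries] = {}
    index = pd.DatetimeIndex(timestamps)
    for col in dialect.channel_columns:
        raw = frame[col].str.strip()
        is_missing = raw.isin(dialect.missing_tokens)
        to_parse = raw.where(~is_missing, "0")
        if dialect.decimal_mark == ",":
            to_parse = to_parse.str.replace(".", "", regex=False).str.replace(
                ",", ".", regex=False
            )
        try:
            # numpy's parser is correctly rounded (exact CSV round trips);
            # pandas.to_numeric is not
            values = to_parse.to_numpy(dtype=str).astype(float)
        except ValueError:
            numeric = pd.to_numeric(to_parse, errors="coerce")
            bad = numeric.isna() & ~is_missing
            i = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else 0
            raise ParseError(
                f"unparsable value {raw.iloc[i]!r} in column {col!r}",
                path=path,
                line=data_lines[i],
            ) from None
        values[is_missing.to_numpy()] = np.nan
        channels[col] = pd.Series(values, index=index)

    start = index[0] if start_time is None else pd.Timestamp(start_time)
    if period is None:
        keep = index >= start
    else:
        keep = (index >= start) & (index < start + pd.Timedelta(period))
    if not keep.any():
        raise EmptySelectionError(
            f"no rows in window starting {start} (period={period}) in {path}"
        )

    series = {
        cname: EpochSeries(s[keep]) if keep.sum() > 1 else EpochSeries(s[keep], _single_epoch_fallback(index))
        for cname, s in channels.items()
    }
    return LightRecording(name if name is not None else path.stem, series)


def _single_epoch_fallback(index: pd.DatetimeIndex) -> pd.Timedelta:
    if len(index) > 1:
        return index[1] - index[0]
    raise ParseError("cannot infer epoch from a single-row file")


def read_batch(
    pattern: str,
    dialect: CsvDialect,
    period=None,
    start_time=None,
) -> tuple[list[LightRecording], list[tuple[str, Exception]]]:
    """Read every file matching a glob pattern, sorted by file name.

    Per-file failures do not abort the batch: the failing files are
    reported in the returned error list as ``(path, exception)`` pairs
    while the remaining recordings are still loaded.
    """
    paths = sorted(_glob.glob(str(pattern)))
    if not paths:
        raise EmptySelectionError(f"pattern {pattern!r} matched no files")
    recordings, failures = [], []
    for p in paths:
        try:
            recordings.append(
                read_recording(p, dialect, start_time=start_time, period=period)
            )
        except Exception as exc:
            failures.append((p, exc))
    return recordings, failures


def read_mask_file(path) -> MaskSpec:
    """Read mask intervals from a JSON document (see module docstring)."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", path=path) from exc
    if not isinstance(doc, dict) or "masks" not in doc:
        raise ParseError('mask file must be an object with a "masks" list', path=path)
    intervals = []
    for i, entry in enumerate(doc["masks"]):
        try:
            start = pd.Timestamp(entry["start"])
            stop = pd.Timestamp(entry["stop"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed mask entry #{i}: {exc}", path=path) from exc
        if pd.isna(start) or pd.isna(stop):
            raise ParseError(f"malformed timestamp in mask entry #{i}", path=path)
        intervals.append((start, stop))
    return MaskSpec(tuple(intervals))


def write_summary(table, path) -> None:
    """Write a metric table to RFC-4180 CSV.

    Header row carries the metric names; the first column holds the
    recording name. Floats are written with 17 significant digits so that
    reading the file back reproduces every value exactly.
    """
    frame = getattr(table, "frame", table)
    if not isinstance(frame, pd.DataFrame):
        raise ParameterError("write_summary expects a MetricTable or DataFrame")
    frame.to_csv(path, float_format="%.17g", index_label="name")
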