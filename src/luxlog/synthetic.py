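"""Seeded generator of realistic wearable light-exposure recordings.

Real-world personal light exposure alternates between bright, strongly
diurnal outdoor light (tens of thousands of lux around solar noon) and
much dimmer, roughly constant indoor light, with heavy-tailed
multiplicative variability and occasional non-wear gaps during which a
wrist device, covered or on a table, records darkness. The generator
emulates exactly these regimes so that every reader, preprocessing step
and metric can be exercised without any external dataset:

* a smooth Gaussian-bell diurnal daylight template on clock time,
  wrapped at midnight,
* an hourly indoor/outdoor Bernoulli state (people are indoors at
  night, sometimes outside during the day),
* multiplicative lognormal intensity noise with a chosen coefficient of
  variation,
* non-wear intervals drawn as a Poisson process with exponential
  durations, recorded as zeros (a covered sensor reads dark, not
  missing) and returned as a ground-truth mask for oracle tests.

Everything is driven by one integer seed; identical parameters give
byte-identical recordings and fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import EpochSeries, LightRecording
from .errors import ParameterError
from .io_text import CsvDialect, MaskSpec

__all__ = ["SyntheticParams", "generate_recording", "write_fixture", "GroundTruth"]

#: Default probability of being outdoors, per clock hour 0..23:
#: zero at night, rising through the morning, highest around lunchtime.
_DEFAULT_OUTDOOR_P = (
    0.0, 0.0, 0.0, 0.0, 0.0, 0.0,  # 00-05
    0.02, 0.10, 0.25, 0.20, 0.20, 0.25,  # 06-11
    0.40, 0.35, 0.25, 0.20, 0.25, 0.30,  # 12-17
    0.15, 0.08, 0.03, 0.0, 0.0, 0.0,  # 18-23
)


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the synthetic light-exposure model.

    Defaults describe a temperate-latitude week of minute-resolution
    wrist-logger data: a 30 klx daylight peak at 13:00 with a 3-h bell
    width, 150 lx indoor light, lognormal noise with CV 1 (light data
    are highly variable), and about one half-hour non-wear gap per day.
    """

    n_days: int = 7
    epoch_length: pd.Timedelta = pd.Timedelta(minutes=1)
    start: pd.Timestamp = pd.Timestamp("2023-03-06 00:00:00")
    daylight_peak: float = 30000.0  # lux
    peak_time: float = 13.0  # clock hours
    daylight_width: pd.Timedelta = pd.Timedelta(hours=3)
    indoor_level: float = 150.0  # lux
    outdoor_probability_by_hour: tuple = _DEFAULT_OUTDOOR_P
    noise_cv: float = 1.0
    nonwear_intervals_per_day: float = 1.0
    nonwear_mean_duration: pd.Timedelta = pd.Timedelta(minutes=30)
    seed: int = 0
    channel_name: str = "White Light"
    name: str = "synthetic"

    def __post_init__(self):
        object.__setattr__(self, "epoch_length", pd.Timedelta(self.epoch_length))
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(
            self, "daylight_width", pd.Timedelta(self.daylight_width)
        )
        object.__setattr__(
            self,
            "nonwear_mean_duration",
            pd.Timedelta(self.nonwear_mean_duration),
        )
        object.__setattr__(
            self,
            "outdoor_probability_by_hour",
            tuple(float(p) for p in self.outdoor_probability_by_hour),
        )
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")
        if pd.Timedelta(days=1).value % self.epoch_length.value != 0:
            raise ParameterError("epoch_length must divide 24 h")
        if self.daylight_peak <= 0 or self.indoor_level <= 0:
            raise ParameterError("level parameters must be positive")
        if self.daylight_width <= pd.Timedelta(0):
            raise ParameterError("daylight_width must be positive")
        if len(self.outdoor_probability_by_hour) != 24 or any(
            not 0.0 <= p <= 1.0 for p in self.outdoor_probability_by_hour
        ):
            raise ParameterError(
                "outdoor_probability_by_hour needs 24 probabilities in [0, 1]"
            )
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.nonwear_intervals_per_day < 0:
            raise ParameterError("nonwear_intervals_per_day must be >= 0")
        if self.nonwear_mean_duration <= pd.Timedelta(0):
            raise ParameterError("nonwear_mean_duration must be positive")

    def with_seed(self, seed: int) -> "SyntheticParams":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for oracle tests.

    ``state`` holds one label per epoch in {"indoor", "outdoor",
    "nonwear"}; ``nonwear`` the true non-wear intervals as a half-open
    :class:`MaskSpec` (clipped to the recording span).
    """

    nonwear: MaskSpec
    state: np.ndarray = field(repr=False, default=None)


def diurnal_template(hours_of_day: np.ndarray, params: SyntheticParams) -> np.ndarray:
    """Gaussian-bell daylight intensity at given clock hours, wrapped at
    midnight (circular distance to the peak)."""
    width_h = params.daylight_width.total_seconds() / 3600.0
    delta = np.abs(hours_of_day - params.peak_time)
    delta = np.minimum(delta, 24.0 - delta)
    return params.daylight_peak * np.exp(-(delta**2) / (2.0 * width_h**2))


def generate_recording(
    params: SyntheticParams,
) -> tuple[LightRecording, GroundTruth]:
    """Simulate one subject's multi-day light recording.

    Per epoch: draw the indoor/outdoor state from the clock-hour
    probability, take the diurnal template (outdoor) or the constant
    indoor level, multiply mean-1 lognormal noise with the requested CV,
    then zero out non-wear intervals drawn as a per-day Poisson process
    with exponentially distributed durations. Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_days * (pd.Timedelta(days=1).value // params.epoch_length.value)
    index = pd.date_range(
        params.start, periods=n, freq=params.epoch_length
    )
    hours = (
        index.hour.to_numpy()
        + index.minute.to_numpy() / 60.0
        + index.second.to_numpy() / 3600.0
    )

    p_out = np.asarray(params.outdoor_probability_by_hour)[index.hour.to_numpy()]
    outdoor = rng.random(n) < p_out
    base = np.where(outdoor, diurnal_template(hours, params), params.indoor_level)

    if params.noise_cv > 0:
        sigma2 = math.log(1.0 + params.noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)
        values = base * noise
    else:
        values = base.astype(float).copy()

    state = np.where(outdoor, "outdoor", "indoor").astype(object)

    # non-wear: per-day Poisson counts, uniform starts, exponential durations
    day_ns = pd.Timedelta(days=1).value
    intervals = []
    mean_dur_s = params.nonwear_mean_duration.total_seconds()
    for day in range(params.n_days):
        k = rng.poisson(params.nonwear_intervals_per_day)
        day_start = params.start.value + day * day_ns
        for _ in range(k):
            start_ns = day_start + int(rng.random() * day_ns)
            dur_ns = int(rng.exponential(mean_dur_s) * 1e9)
            intervals.append(
                (
                    pd.Timestamp(start_ns),
                    pd.Timestamp(min(start_ns + max(dur_ns, 1), index[-1].value + params.epoch_length.value)),
                )
            )
    intervals.sort()
    ts_ns = index.asi8
    for start, stop in intervals:
        hit = (ts_ns >= start.value) & (ts_ns < stop.value)
        values[hit] = 0.0
        state[hit] = "nonwear"

    series = EpochSeries(pd.Series(values, index=index), params.epoch_length)
    recording = LightRecording(params.name, {params.channel_name: series})
    truth = GroundTruth(nonwear=MaskSpec(tuple(intervals)), state=state)
    return recording, truth


def write_fixture(recording: LightRecording, path, dialect: CsvDialect) -> None:
    """Write a recording as a CSV fixture readable under the same dialect.

    Values are printed with 17 significant digits so the io round trip is
    exact; the decimal mark follows the dialect.
    """
    names = recording.get_channel_list()
    missing = [c for c in dialect.channel_columns if c not in names]
    if missing:
        raise ParameterError(
            f"dialect channels {missing} not present in recording {names}"
        )
    fmt = dialect.timestamp_format or "%Y-%m-%d %H:%M:%S"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            dialect.delimiter.join(
                [dialect.timestamp_column, *dialect.channel_columns]
            )
            + "\n"
        )
        columns = [recording.get_channel(c).values for c in dialect.channel_columns]
        for i, ts in enumerate(recording.timestamps):
            cells = [ts.strftime(fmt)]
            for col in columns:
                v = col[i]
                if np.isnan(v):
                    cells.append(dialect.missing_tokens[0] if dialect.missing_tokens else "")
                else:
                    text = f"{v:.17g}"
                    if dialect.decimal_mark == ",":
                        text = text.replace(".", ",")
                    cells.append(text)
            fh.write(dialect.delimiter.join(cells) + "\n")
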