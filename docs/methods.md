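# Methods

## Data model

A recording is a set of channels sharing one time axis: strictly
increasing, timezone-naive local timestamps at a constant epoch
(typically 15 s – 60 s). Construction rejects irregular spacing rather
than silently resampling, because every metric formula below assumes a
constant epoch. Clock time is used throughout — the circadian metrics
are defined on time-of-day — and daylight-saving transitions are not
modelled; recordings spanning a DST change should be split or shifted
by the caller.

Missing values (`NaN`) and masked epochs are equivalent everywhere
downstream: both are excluded from every sum, count and variance. Mask
intervals are half-open `[start, stop)` and combine by union; applying
masks is therefore commutative and idempotent, and masking can never
un-mask an epoch.

Raw intensities must be non-negative (a light sensor cannot report
negative flux) and ingestion enforces this. Two transforms legitimately
produce signed output — the base-10 log of values below 1, and
zero-phase filtering, whose ringing is deliberately not clipped — so
transform results relax the sign constraint internally. Metrics are
indifferent to sign.

### Day folding

Daily period `h` (1-based, `h = 1..p`) covers the half-open clock
interval `[(h−1)·Δ, h·Δ)` where `Δ` is the epoch — the epoch-start
convention. The daily profile is the per-`h` mean of all valid values;
folding is anchored at the midnight preceding the first sample, so for
a 24-h fold the index is exactly the time-of-day index, and the
weighted mean of the profile (weights = per-period counts) equals the
grand mean to machine precision. Whether leading/trailing partial days
are dropped before folding is a caller decision (`whole_days_only`),
exposed as a flag because field practice varies; the default keeps all
data, letting partial days contribute fewer observations to the
affected periods.

## Metric conventions

**Strict thresholds.** "Above threshold" means `value > C` in every
operation (thresholding, binarization, TAT, MLiT, exposure level). The
choice is arbitrary for continuous data (ties have measure zero) but
making it uniform yields exact identities used by the tests, e.g.
`TAT(C) = Δ · Σ binarize(series, C)` and "count of ones after
binarization = count of survivors after threshold-filtering".

**MLiT.** The fractional index is the indicator-weighted mean of the
1-based daily period index, pooled over days. Reported clock time is
`(index − 1)·Δ` after midnight, consistent with the epoch-start
convention. Missing epochs contribute zero to numerator and
denominator; if no epoch exceeds `C` the index is NaN rather than an
error, since an all-dim recording is a legitimate observation.

**L5/M10.** Computed on the averaged daily profile (not per-day, not
on the raw multi-day series) with circular windows, which matches the
nonparametric circadian tradition and makes the result deterministic.
All `p` onsets are scanned; ties break to the earliest onset in
[00:00, 24:00). A candidate window containing a missing profile period
is excluded; if every candidate is excluded the metric raises a typed
insufficient-data error. Note that on exactly symmetric profiles two
windows can tie in exact arithmetic, in which case floating-point
summation order decides between adjacent onsets — tests avoid
constructing such knife-edge profiles.

**IS / IV.** The equations assume complete data. The natural
generalisation used here: IS averages `(x̄_h − x̄)²` over the daily
periods that have at least one valid value and `(x_i − x̄)²` over the
valid samples; IV sums squared first differences only over adjacent
pairs where both epochs are valid, with the pair count replacing
`n − 1`. For complete data both reduce exactly to the textbook
formulas. A constant series makes both metrics 0/0; this is detected
exactly (zero range of the valid values, not a float tolerance) and
raised as a typed undefined-metric error — which the batch table layer
converts to a missing cell so group runs never abort.

`is_at_period` evaluates the identical code path with an arbitrary
folding period, making IS literally the 24-h value of the chi-square
periodogram normalised by the number of valid samples; scanning the
test period locates the dominant rhythm.

Because IS and IV are frequency-sensitive (IS of minute-level noise is
far lower than of the hourly means of the same data), resampling before
evaluation is an explicit caller parameter (`freq`, mean aggregation),
conventionally `'1h'`.

## Preprocessing choices

- **Resampling** requires the new epoch to be an integer multiple of
  the old one; blocks are left-labelled (block start), consistent with
  the epoch-start convention. Aggregation ignores missing values; an
  all-missing block stays missing (in particular `sum` uses a
  min-count of one, so gaps do not silently become zeros).
- **Butterworth filtering** is zero-phase (forward–backward
  second-order sections), so the effective gain is the squared
  magnitude of the designed response and the phase is exactly zero.
  Cutoffs are given in cycles per day and checked against the Nyquist
  frequency of the epoch. Order defaults to 3. The input must be
  gap-free: interpolating across non-wear gaps is a modelling decision
  the package refuses to make implicitly.
- **Log transform** is `log10(value + offset)` with offset 1 by
  convention, mapping darkness to 0; thresholds on the log scale are
  then `log10(C_lux + offset)`, the idiom the CLI's `lux:` token
  implements.

## Synthetic recordings

The generator emulates the regimes that dominate real personal light
exposure: a smooth Gaussian-bell daylight template on clock time
(default peak 30 klx at 13:00, SD 3 h, wrapped at midnight), a
per-epoch indoor/outdoor Bernoulli state driven by a 24-value hourly
probability table (zero at night, maximal around midday), constant
indoor light (150 lx), multiplicative mean-1 lognormal noise
(`CV = 1`; field light data are heavy-tailed), and non-wear intervals
drawn per day as a Poisson process (1/day) with exponential durations
(mean 30 min). Defaults are one week at 1-min epochs. Non-wear epochs
record **zero**, not missing — a covered sensor reads dark — and the
true intervals and per-epoch state labels are returned so tests can
verify masking recovers exactly the corrupted epochs.

One integer seed drives a single `numpy` PCG64 stream; identical
parameters give byte-identical fixtures.

What the generator does *not* emulate: weather and season, geolocation
and photoperiod changes, spectral composition (no melanopic channel
modelling), sensor saturation and calibration error, and posture or
sleeve-cover artefacts other than the zeroed non-wear intervals.
Passing tests therefore demonstrate correctness of the *computations*
on realistic magnitudes and gap structure, not validity of any
scientific conclusion about real populations.

## Numerical notes

- Summary CSVs are written with 17 significant digits and fixtures are
  parsed with a correctly-rounded string→float conversion, so
  write/read round trips are bit-exact.
- Metric failures in batch tables become missing cells plus an error
  report; only an empty recording list or an unknown metric is fatal.
- Simulation sizes used by the test suite and the acceptance script
  (e.g. 100 random series for the MLiT oracle, 200 seeds for the IS
  noise limit, 100 seeds × 10⁴ samples for the IV noise limit, 5
  subjects × 7 days for the end-to-end run) were chosen to pin each
  statistic well inside its theoretical tolerance band while keeping
  the whole suite runnable in seconds.

## Known limitations

- No vendor binary formats; data must be exported to delimited text.
- No automatic non-wear detection — masking is manual/file-based by
  design, since there is no consensus algorithm for light data.
- No spectral (α-opic) conversions; the metrics are agnostic to which
  intensity quantity the logger recorded.
- No timezone conversion or DST handling.
- IS/IV values are comparable between recordings only at a common
  evaluation epoch; the package does not enforce one.
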