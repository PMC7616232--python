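# luxlog

Device-agnostic analysis of **wearable light-logger and dosimeter
recordings**: fixed-epoch time series of personal light exposure
(illuminance, mEDI, or any other per-epoch intensity) recorded by
wrist-worn actimeters, pendants or near-corneal loggers.

Light is the dominant *zeitgeber* of the human circadian system, and a
growing number of studies relate individual light-exposure patterns to
sleep, mood and health outcomes. Those studies all need the same
plumbing — reading heterogeneous CSV exports, masking non-wear periods,
resampling and filtering — followed by a small canon of exposure
metrics. `luxlog` provides both halves as a plain Python library plus a
batch CLI, with a seeded synthetic-recording generator so every step is
testable without any proprietary dataset.

## Metrics

For a recording with intensities `x_i` at `n` epochs (`p` epochs per
day, daily-period means `x̄_h`, grand mean `x̄`), with all threshold
comparisons strict (`x > C`):

- **Summary statistics** — mean, median, SD, min/max, percentiles over
  the recording or arbitrary windows.
- **Light exposure level** — mean intensity, optionally restricted to
  epochs above a threshold `C`.
- **TAT(C)** — time above threshold: `epoch_length × #{x_i > C}`.
- **MLiT(C)** — mean light timing above threshold (Reid et al.): the
  indicator-weighted mean daily-period index

  `MLiT(C) = Σ_j Σ_k j·I_jk(C) / Σ_j Σ_k I_jk(C)`,

  where `I_jk = 1` iff the intensity in daily period `j` of day `k`
  exceeds `C` (`j = 1..m`, `m = 1440` for minute data).
- **L5 / M10** — onset and mean of the 5-h window of least and the
  10-h window of maximal exposure on the average daily profile
  (circular windows, earliest-onset tie-break).
- **IS** — interdaily stability,
  `IS = n·Σ_h (x̄_h − x̄)² / (p·Σ_i (x_i − x̄)²)`, the 24-h value of the
  chi-square periodogram normalised by `n` (`is_at_period` evaluates it
  at any folding period); 1 for a perfectly repeated daily pattern,
  ≈ 1/d for d days of noise.
- **IV** — intradaily variability,
  `IV = n·Σ (x_{i+1} − x_i)² / ((n−1)·Σ (x_i − x̄)²)`; ≈ 2 for white
  noise, → 0 for smooth profiles.

Preprocessing: interval masking from JSON files, window truncation,
block resampling (sum/mean/median/min/max), zero-phase Butterworth
filtering (cutoffs in cycles/day), base-10 log transform with offset,
thresholding and binarization.

## Worked example

```python
from math import log10
from luxlog import (SyntheticParams, generate_recording, log_transform,
                    light_exposure_level, tat, mlit, l5m10,
                    interdaily_stability, intradaily_variability)

params = SyntheticParams(n_days=7, seed=42)       # one synthetic subject
recording, truth = generate_recording(params)
series = log_transform(recording.get_channel("White Light"), 1.0)

level = light_exposure_level(series, log10(100 + 1))
minutes = tat(series, log10(100 + 1), "minute")
timing = mlit(series, log10(500 + 1))
l5, m10 = l5m10(series)
print(f"Level_100 : {level:.3f} log10(lx)")
print(f"TAT_100   : {minutes:.0f} min over {params.n_days} days")
print(f"MLiT_500  : index {timing.index:.1f} -> {timing.clock_time}")
print(f"M10       : onset {m10.onset}, mean {m10.mean_value:.3f}")
print(f"IS        : {interdaily_stability(series, freq='1h'):.3f}")
print(f"IV        : {intradaily_variability(series, freq='1h'):.3f}")
```

prints

```
Level_100 : 2.680 log10(lx)
TAT_100   : 5820 min over 7 days
MLiT_500  : index 787.3 -> 0 days 13:06:16.060209424
M10       : onset 0 days 08:21:00, mean 2.554
IS        : 0.662
IV        : 0.751
```

Read: on the log scale the subject averages ~10^2.68 ≈ 480 lx during
supra-100-lx epochs, spends 5820 minutes above 100 lx across the week,
and the supra-500-lx exposure is centred at 13:06 — consistent with the
generator's 13:00 daylight peak; the brightest 10 hours start at 08:21.
An IS of 0.66 says the daily pattern repeats fairly stably; an IV of
0.75 is far below the white-noise value of 2.

The same analysis from the shell, for a batch of subjects:

```
luxlog simulate --n-subjects 5 --output-dir fixtures --seed 11
luxlog metrics --input 'fixtures/*.csv' --channel "White Light" \
    --period 6D --log10-offset 1.0 \
    --metric 'exposure_level:threshold=lux:100' \
    --metric 'tat:threshold=lux:100,oformat=minute' \
    --metric 'mlit:threshold=lux:500' \
    --output tab1.csv
```

writes a 5-row summary CSV (columns `Level_100`, `TAT_100`,
`MLit_500`) plus a JSON run manifest. `threshold=lux:100` means
"100 lx on the analysis scale": with `--log10-offset 1.0` it becomes
`log10(100 + 1)`.

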