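"""Exposure metrics against independent oracles and closed forms."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from luxlog import (
    DailyProfile,
    MetricSpec,
    binarize,
    compute_metric_table,
    interdaily_stability,
    intradaily_variability,
    is_at_period,
    l5m10,
    light_exposure_level,
    mlit,
    summary_statistics,
    tat,
    tat_per_window,
)
from luxlog.metrics import extreme_window
from luxlog.errors import (
    InsufficientDataError,
    ParameterError,
    UndefinedMetricError,
)

from conftest import T0, make_recording, make_series


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_mlit(values, epoch_minutes, C):
    """Literal double sum over days k and daily periods j, exact rationals."""
    m = 1440 // epoch_minutes
    num, den = 0, 0
    for i, v in enumerate(values):
        j = (i % m) + 1  # series in these tests starts at midnight
        if not np.isnan(v) and v > C:
            num += j
            den += 1
    if den == 0:
        return None
    return Fraction(num, den)


def brute_force_window(profile_values, w, kind):
    p = len(profile_values)
    best_onset, best_mean = None, None
    for onset in range(p):
        window = [profile_values[(onset + i) % p] for i in range(w)]
        if any(np.isnan(v) for v in window):
            continue
        mean = sum(window) / w
        better = (
            best_mean is None
            or (kind == "min" and mean < best_mean)
            or (kind == "max" and mean > best_mean)
        )
        if better:
            best_onset, best_mean = onset, mean
    return best_onset, best_mean


# ---------------------------------------------------------------------------


class TestSummaryStatistics:
    def test_constant_series(self):
        row = summary_statistics(make_series([7.0] * 10))
        assert row["mean"] == row["median"] == 7.0
        assert row["std"] == 0.0

    def test_one_to_hundred(self):
        row = summary_statistics(make_series(np.arange(1.0, 101.0)))
        assert row["mean"] == 50.5
        assert row["median"] == 50.5

    def test_windows_match_slice_recomputation(self, rng):
        values = rng.uniform(0, 100, size=120)
        s = make_series(values)
        w1 = (T0, T0 + pd.Timedelta("40min"))
        w2 = (T0 + pd.Timedelta("60min"), T0 + pd.Timedelta("120min"))
        row = summary_statistics(s, windows=[w1, w2])
        assert row[f"mean@{w1[0].isoformat()}"] == pytest.approx(np.mean(values[:40]))
        assert row[f"median@{w2[0].isoformat()}"] == pytest.approx(
            np.median(values[60:])
        )

    def test_empty_window_gives_missing_cells(self):
        s = make_series([1.0, 2.0])
        far = (T0 + pd.Timedelta("1d"), T0 + pd.Timedelta("2d"))
        row = summary_statistics(s, windows=[far])
        assert row.isna().all()


class TestExposureLevel:
    def test_thresholded_mean(self):
        assert light_exposure_level(make_series([0, 5, 2, 7]), 2.0) == 6.0

    def test_low_threshold_reduces_to_plain_mean(self):
        s = make_series([1.0, 2.0, 3.0])
        assert light_exposure_level(s, 0.5) == light_exposure_level(s)

    def test_threshold_above_max_is_missing(self):
        assert math.isnan(light_exposure_level(make_series([1.0, 2.0]), 10.0))


class TestTAT:
    def test_always_above_two_days_of_minutes(self):
        s = make_series([50.0] * 2880)
        assert tat(s, 10.0, "minute") == 2880.0

    def test_never_above(self):
        assert tat(make_series([1.0] * 100), 10.0, "minute") == 0.0

    def test_formats_consistent(self):
        s = make_series([0, 5, 2, 7])
        assert tat(s, 2.0, "count") == 2
        assert tat(s, 2.0, "minute") == 2.0
        assert tat(s, 2.0, "timedelta") == pd.Timedelta("2min")

    def test_unknown_format_rejected(self):
        with pytest.raises(ParameterError):
            tat(make_series([1.0]), 0.0, "hours")

    def test_binarize_sum_identity_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 300))
            values = rng.lognormal(3, 2, size=n)
            values[rng.random(n) < 0.1] = np.nan
            C = float(rng.uniform(0, 200))
            s = make_series(values)
            expected = np.nansum(binarize(s, C).values) * 1.0  # minutes at 1-min epoch
            assert tat(s, C, "minute") == expected

    def test_per_window_additivity(self, rng):
        values = rng.lognormal(3, 2, size=200)
        s = make_series(values)
        half = T0 + pd.Timedelta("100min")
        end = T0 + pd.Timedelta("200min")
        row = tat_per_window(s, 50.0, [(T0, half), (half, end)])
        assert row.sum() == tat(s, 50.0, "minute")

    def test_per_window_brute_force(self, rng):
        values = rng.lognormal(2, 1.5, size=300)
        s = make_series(values)
        windows = [
            (T0 + pd.Timedelta("17min"), T0 + pd.Timedelta("63min")),
            (T0 + pd.Timedelta("100min"), T0 + pd.Timedelta("131min")),
        ]
        row = tat_per_window(s, 10.0, windows, "count")
        for (start, stop), got in zip(windows, row):
            i0 = int((start - T0).total_seconds() // 60)
            i1 = int((stop - T0).total_seconds() // 60)
            assert got == int(np.sum(values[i0:i1] > 10.0))


class TestMLiT:
    def test_single_exceedance_at_1300(self):
        values = np.zeros(1440)
        values[13 * 60] = 100.0  # minute covering 13:00
        res = mlit(make_series(values), 10.0)
        assert res.clock_time == pd.Timedelta(hours=13)
        assert res.exceedance_count == 1

    def test_two_day_worked_case(self):
        """Exceedances at minute-index 601 (day 1) and 721 (day 2) -> 661 = 11:00."""
        values = np.zeros(2 * 1440)
        values[600] = 100.0  # j = 601 on day 1
        values[1440 + 720] = 100.0  # j = 721 on day 2
        res = mlit(make_series(values), 10.0)
        assert res.index == (601 + 721) / 2
        assert res.clock_time == pd.Timedelta(hours=11)
        assert res.m == 1440
        assert res.n == 2

    def test_symmetric_exceedances_center_on_noon(self):
        values = np.zeros(1440)
        values[11 * 60] = values[13 * 60 - 1] = 100.0  # symmetric about noon
        res = mlit(make_series(values), 10.0)
        assert res.clock_time == pd.Timedelta(hours=12) - pd.Timedelta("30s")
        # epoch-start convention: indices 661 and 780 average to 720.5

    def test_no_exceedance(self):
        res = mlit(make_series([1.0] * 1440), 10.0)
        assert math.isnan(res.index)
        assert res.clock_time is None
        assert res.exceedance_count == 0

    def test_brute_force_oracle_random(self, rng):
        for _ in range(100):
            epoch_min = int(rng.choice([24, 30, 48, 60, 144]))  # 10-60 periods/day
            n_days = int(rng.integers(2, 6))
            n = n_days * (1440 // epoch_min)
            values = rng.lognormal(2, 2, size=n)
            values[rng.random(n) < 0.1] = np.nan
            C = float(rng.uniform(0, 60))
            s = make_series(values, epoch=f"{epoch_min}min")
            expected = brute_force_mlit(values, epoch_min, C)
            res = mlit(s, C)
            if expected is None:
                assert math.isnan(res.index)
            else:
                assert res.index == expected.numerator / expected.denominator
                assert 1 <= res.index <= res.m

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.lognormal(2, 1.5, size=3 * 1440)
        s = make_series(values)
        C = 10.0
        base = mlit(s, C)
        logged = mlit(
            make_series(np.log10(values + 1.0)), math.log10(C + 1.0)
        )
        assert base.index == logged.index
        assert base.exceedance_count == logged.exceedance_count


class TestL5M10:
    def test_square_wave_profile(self):
        values = np.tile(
            np.where((np.arange(24) >= 8) & (np.arange(24) < 18), 1000.0, 0.0), 3
        )
        l5, m10 = l5m10(make_series(values, epoch="1h"))
        assert m10.onset == pd.Timedelta(hours=8)
        assert m10.mean_value == 1000.0
        assert l5.mean_value == 0.0
        assert l5.onset == pd.Timedelta(0)  # earliest all-zero onset

    def test_constant_profile_tie_break(self):
        l5, m10 = l5m10(make_series([5.0] * 48, epoch="1h"))
        assert l5.onset == m10.onset == pd.Timedelta(0)
        assert l5.mean_value == m10.mean_value == 5.0

    def test_sinusoid_peak_geometry(self):
        # peak at 12:30 so the discrete hourly grid has a unique optimum
        hours = np.arange(3 * 24)
        values = 100.0 * (1.0 + np.cos(2 * np.pi * (hours % 24 - 12.5) / 24))
        l5, m10 = l5m10(make_series(values, epoch="1h"))
        assert m10.onset == pd.Timedelta(hours=8)  # window 08:00-18:00, centre 12:30
        # trough at 00:30: the two centred 5-h windows tie in exact arithmetic
        assert l5.onset in (pd.Timedelta(hours=22), pd.Timedelta(hours=23))

    def test_exhaustive_scan_oracle(self, rng):
        for _ in range(50):
            p = int(rng.choice([24, 48, 96]))
            profile = DailyProfile(
                period_means=rng.uniform(0, 1000, size=p),
                epoch_length=pd.Timedelta(hours=24 / p),
                n_days_used=1,
            )
            for length, kind in ((pd.Timedelta(hours=5), "min"), (pd.Timedelta(hours=10), "max")):
                w = int(length / profile.epoch_length)
                onset, mean = brute_force_window(profile.period_means, w, kind)
                res = extreme_window(profile, length, kind)
                assert res.onset == onset * profile.epoch_length
                assert res.mean_value == pytest.approx(mean, rel=1e-12)

    def test_bracketing_invariant(self, rng):
        values = rng.uniform(0, 500, size=4 * 24)
        s = make_series(values, epoch="1h")
        l5, m10 = l5m10(s)
        overall = np.mean(values)
        assert l5.mean_value <= overall + 1e-9
        assert m10.mean_value >= overall - 1e-9

    def test_gappy_profile_insufficient_data(self):
        profile = DailyProfile(
            period_means=np.full(24, np.nan),
            epoch_length=pd.Timedelta(hours=1),
            n_days_used=1,
        )
        with pytest.raises(InsufficientDataError):
            extreme_window(profile, pd.Timedelta(hours=5), "min")


class TestIS:
    def test_periodic_pattern_is_one(self, rng):
        pattern = rng.uniform(0, 100, size=24)
        s = make_series(np.tile(pattern, 7), epoch="1h")
        assert interdaily_stability(s) == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedMetricError):
            interdaily_stability(make_series([5.0] * 48, epoch="1h"))

    def test_iid_noise_mean_is_one_over_days(self, rng):
        d = 7
        values = [
            interdaily_stability(
                make_series(rng.standard_normal(d * 24), epoch="1h")
            )
            for _ in range(200)
        ]
        assert np.mean(values) == pytest.approx(1 / d, abs=0.02)

    def test_bounded_unit_interval(self, rng):
        for _ in range(20):
            s = make_series(rng.lognormal(1, 1, size=5 * 24), epoch="1h")
            v = interdaily_stability(s)
            assert -1e-9 <= v <= 1 + 1e-9

    def test_resampling_option_matches_explicit(self, rng):
        from luxlog import resample

        values = rng.lognormal(2, 1, size=3 * 1440)
        s = make_series(values)
        assert interdaily_stability(s, freq="1h") == interdaily_stability(
            resample(s, "1h", "mean")
        )


class TestIV:
    def test_alternating_is_exactly_four(self):
        values = np.tile([1.0, -1.0], 120)
        assert intradaily_variability(make_series(values)) == 4.0

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedMetricError):
            intradaily_variability(make_series([3.0] * 100))

    def test_hourly_sinusoid_closed_form(self):
        hours = np.arange(28 * 24)
        s = make_series(np.sin(2 * np.pi * hours / 24), epoch="1h")
        expected = 4 * math.sin(math.pi / 24) ** 2
        assert intradaily_variability(s) == pytest.approx(expected, rel=0.01)

    def test_iid_gaussian_near_two(self, rng):
        values = [
            intradaily_variability(make_series(rng.standard_normal(10_000)))
            for _ in range(100)
        ]
        assert 1.95 <= np.mean(values) <= 2.05

    def test_missing_pairs_skipped(self):
        # gap splits the series; diffs across the gap are not formed
        values = np.array([0.0, 2.0, np.nan, 0.0, 2.0, 0.0])
        got = intradaily_variability(make_series(values))
        diffs = np.array([2.0, 2.0, -2.0])  # valid adjacent pairs only
        x = np.array([0, 2, 0, 2, 0.0])
        expected = np.mean(diffs**2) / np.mean((x - x.mean()) ** 2)
        assert got == pytest.approx(expected, rel=1e-12)


class TestIsAtPeriod:
    def test_24h_equals_interdaily_stability(self, rng):
        for _ in range(20):
            n_days = int(rng.integers(2, 6))
            values = rng.lognormal(1, 1, size=n_days * 24)
            s = make_series(values, epoch="1h")
            assert is_at_period(s, "24h") == interdaily_stability(s)

    def test_12h_periodic_series(self, rng):
        pattern = rng.uniform(0, 10, size=12)
        s = make_series(np.tile(pattern, 10), epoch="1h")
        assert is_at_period(s, "12h") == pytest.approx(1.0, abs=1e-9)

    def test_periodogram_peaks_at_injected_period(self, rng):
        hours = np.arange(10 * 24)
        values = 5 * np.sin(2 * np.pi * hours / 24) + rng.standard_normal(len(hours))
        s = make_series(values, epoch="1h")
        scanned = {
            h: is_at_period(s, pd.Timedelta(hours=h)) for h in (8, 12, 20, 24, 30)
        }
        assert max(scanned, key=scanned.get) == 24


class TestMetricTable:
    def _recordings(self, rng, n=3):
        recs = []
        for i in range(n):
            values = rng.lognormal(3, 2, size=2 * 1440)
            recs.append(make_recording(values, name=f"rec{i}"))
        return recs

    def test_table_shape_and_against_direct_calls(self, rng):
        recs = self._recordings(rng)
        C1, C2 = math.log10(101), math.log10(501)
        spec = [
            MetricSpec("exposure_level", {"C": C1}, "Level_100"),
            MetricSpec("tat", {"C": C1, "output_format": "minute"}, "TAT_100"),
            MetricSpec("mlit", {"C": C2}, "MLit_500"),
        ]
        # same preprocessing as the batch path: log10(x + 1)
        from luxlog import log_transform

        logged = [
            make_recording(
                np.log10(r.get_channel("White Light").values + 1), name=r.name
            )
            for r in recs
        ]
        table = compute_metric_table(logged, "White Light", spec)
        assert table.frame.shape == (3, 3)
        assert list(table.frame.columns) == ["Level_100", "TAT_100", "MLit_500"]
        for rec in logged:
            s = rec.get_channel("White Light")
            assert table.frame.loc[rec.name, "Level_100"] == light_exposure_level(s, C1)
            assert table.frame.loc[rec.name, "TAT_100"] == tat(s, C1, "minute")
            assert table.frame.loc[rec.name, "MLit_500"] == mlit(s, C2).index

    def test_single_cell_reduction(self, rng):
        rec = self._recordings(rng, n=1)[0]
        table = compute_metric_table([rec], "White Light", [("tat", {"C": 100.0})])
        assert table.frame.shape == (1, 1)
        assert table.frame.iloc[0, 0] == tat(rec.get_channel("White Light"), 100.0)

    def test_failing_metric_leaves_missing_cell(self):
        good = make_recording(np.arange(48.0), epoch="1h", name="good")
        constant = make_recording([5.0] * 48, epoch="1h", name="flat")
        table = compute_metric_table(
            [good, constant], "White Light", [("is", {}), ("mean", {})]
        )
        assert math.isnan(table.frame.loc["flat", "is"])
        assert not math.isnan(table.frame.loc["flat", "mean"])
        assert not math.isnan(table.frame.loc["good", "is"])
        assert any(name == "flat" for name, _, _ in table.errors)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ParameterError):
            compute_metric_table([], "White Light", [("mean", {})])
        with pytest.raises(ParameterError):
            compute_metric_table(
                [make_recording([1.0, 2.0])], "White Light", []
            )


class TestMaskRemovalEquivalence:
    def test_order_free_metrics_match_physical_removal(self, rng):
        """Masked epochs contribute nothing: blanking them equals deleting them
        for order-free metrics (mean, exposure level, TAT)."""
        for _ in range(50):
            n = 240
            values = rng.lognormal(2, 1.5, size=n)
            mask = rng.random(n) < rng.uniform(0.05, 0.5)
            if mask.all():
                mask[0] = False
            rec = make_recording(values)
            rec.mask[:] = mask
            blanked = rec.get_channel("White Light", masked=True)
            kept = values[~mask]
            C = float(rng.uniform(0, 30))
            assert light_exposure_level(blanked) == pytest.approx(
                np.mean(kept), rel=1e-12
            )
            level = light_exposure_level(blanked, C)
            above = kept[kept > C]
            if above.size:
                assert level == pytest.approx(np.mean(above), rel=1e-12)
            else:
                assert math.isnan(level)
            assert tat(blanked, C, "count") == int(np.sum(kept > C))
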