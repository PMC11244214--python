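"""Humidity correction, trimming, temporal medians, background subtraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lurpm.preprocess import (
    CorrectionParams,
    PreprocessConfig,
    SensorTrack,
    correct_pm,
    correction_factor,
    preprocess_track,
    subtract_background,
    temporal_median,
    trim_outliers,
)


def make_track(pm, rh=60.0, dt=2.0):
    pm = np.asarray(pm, dtype=float)
    n = len(pm)
    rh = np.broadcast_to(np.asarray(rh, dtype=float), (n,))
    return SensorTrack(
        data=pd.DataFrame(
            {
                "time": np.arange(n) * dt,
                "x": np.linspace(0, 100, n),
                "y": np.zeros(n),
                "pm25_raw": pm,
                "temp_c": np.full(n, 20.0),
                "rh_pct": rh,
            }
        )
    )


class TestCorrectionFactor:
    def test_zero_kappa_gives_unity(self):
        params = CorrectionParams(kappa=0.0, rho=1.6)
        rh = np.array([0.1, 0.5, 0.9])
        assert np.allclose(correction_factor(rh, params), 1.0)

    def test_hand_computed_value(self):
        # (0.4 / 1.6) / (1/0.8 - 1) = 0.25 / 0.25 = 1, so C = 2
        c = correction_factor(0.8, CorrectionParams(kappa=0.4, rho=1.6))
        assert c == pytest.approx(2.0, abs=1e-12)

    def test_dry_limit(self):
        c = correction_factor(1e-9, CorrectionParams(kappa=0.4, rho=1.6))
        assert c == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rh", [0.0, 1.0, -0.2, 1.5])
    def test_out_of_range_rh_rejected(self, rh):
        with pytest.raises(ValueError):
            correction_factor(rh, CorrectionParams())

    @given(st.floats(0.01, 0.98), st.floats(0.001, 0.97))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_monotone_nondecreasing_in_rh(self, rh, delta):
        params = CorrectionParams(kappa=0.3, rho=1.5)
        hi = min(rh + delta, 0.99)
        assert correction_factor(hi, params) >= correction_factor(rh, params)


class TestCorrectPm:
    def test_zero_kappa_identity(self):
        track = make_track([5.0, 10.0, 20.0])
        out = correct_pm(track, CorrectionParams(kappa=0.0))
        assert np.allclose(out.data["pm25_corrected"], track.data["pm25_raw"])

    def test_halves_at_factor_two(self):
        track = make_track([20.0] * 3, rh=80.0)
        out = correct_pm(track, CorrectionParams(kappa=0.4, rho=1.6))
        assert np.allclose(out.data["pm25_corrected"], 10.0)

    def test_missing_rh_samples_excluded(self):
        track = make_track([1.0, 2.0, 3.0], rh=[50.0, np.nan, 70.0])
        out = correct_pm(track, CorrectionParams())
        assert len(out) == 2

    def test_roundtrip_recovers_dry_series(self, rng):
        """Inflating by C(kappa_true) then correcting with the same kappa
        must return the dry series to machine precision."""
        dry = rng.uniform(2.0, 40.0, size=200)
        rh = rng.uniform(30.0, 90.0, size=200)
        params = CorrectionParams(kappa=0.4, rho=1.6)
        raw = dry * correction_factor(rh / 100.0, params)
        out = correct_pm(make_track(raw, rh=rh), params)
        rel = np.abs(out.data["pm25_corrected"].to_numpy() - dry) / dry
        assert rel.max() <= 1e-9


class TestTrimOutliers:
    def test_matches_sort_based_oracle(self, rng):
        values = rng.normal(size=123)
        frac = 0.05
        kept = trim_outliers(values, frac)
        # independent oracle: interpolated order statistics from the sort
        s = np.sort(values)
        h_lo = (len(s) - 1) * frac
        h_hi = (len(s) - 1) * (1 - frac)
        lo = s[int(h_lo)] + (h_lo % 1) * (s[int(h_lo) + 1] - s[int(h_lo)])
        hi = s[int(h_hi)] + (h_hi % 1) * (s[int(h_hi) + 1] - s[int(h_hi)])
        expected = values[(values >= lo) & (values <= hi)]
        assert np.array_equal(np.sort(kept), np.sort(expected))

    def test_one_to_hundred(self):
        kept = trim_outliers(np.arange(1.0, 101.0), 0.05)
        assert kept.min() >= 5.95 - 1e-12 and kept.max() <= 95.05 + 1e-12
        assert len(kept) == 90

    def test_constant_series_unchanged(self):
        values = np.full(30, 7.0)
        assert len(trim_outliers(values, 0.05)) == 30

    def test_zero_fraction_unchanged(self, rng):
        values = rng.normal(size=50)
        assert len(trim_outliers(values, 0.0)) == 50

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            trim_outliers(np.arange(10.0), 0.05)


class TestTemporalMedian:
    def test_constant_series(self):
        track = make_track([4.0] * 60)
        df = correct_pm(track, CorrectionParams(kappa=0.0)).data
        out = temporal_median(df, 30.0)
        assert np.allclose(out["pm25_corrected"], 4.0)

    def test_two_second_sampling_gives_15_per_window(self):
        track = make_track(np.arange(60.0), dt=2.0)
        df = correct_pm(track, CorrectionParams(kappa=0.0)).data
        out = temporal_median(df, 30.0)
        assert list(out["n"]) == [15, 15, 15, 15]

    def test_median_is_outlier_robust(self):
        df = pd.DataFrame(
            {"time": [0.0, 1.0, 2.0], "x": [0, 1, 2], "y": [0, 0, 0],
             "pm25_corrected": [1.0, 2.0, 100.0]}
        )
        out = temporal_median(df, 30.0)
        assert out["pm25_corrected"].iloc[0] == 2.0

    def test_short_final_window_kept(self):
        track = make_track(np.arange(16.0), dt=2.0)  # 32 s span
        df = correct_pm(track, CorrectionParams(kappa=0.0)).data
        out = temporal_median(df, 30.0)
        assert len(out) == 2 and out["n"].iloc[-1] == 1


class TestSubtractBackground:
    def test_constant_series(self):
        local, bg = subtract_background(np.full(10, 3.0), 0.05)
        assert bg == 3.0 and np.allclose(local, 0.0)

    def test_interpolated_quantile_background(self):
        local, bg = subtract_background(np.array([10.0, 10, 10, 10, 110]), 0.05)
        assert bg == pytest.approx(10.0)
        assert np.allclose(local, [0, 0, 0, 0, 100])

    @given(st.floats(-50, 50))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_shift_invariance(self, offset):
        rng = np.random.default_rng(1)
        values = rng.normal(size=80)
        local_a, _ = subtract_background(values, 0.05)
        local_b, _ = subtract_background(values + offset, 0.05)
        assert np.allclose(local_a, local_b, atol=1e-10)


class TestPipelineOrder:
    def test_preprocess_equals_manual_composition(self, rng):
        """The fixed order is correct -> trim -> median -> subtract."""
        dry = rng.uniform(5.0, 30.0, size=300)
        rh = rng.uniform(40.0, 80.0, size=300)
        params = CorrectionParams(kappa=0.4, rho=1.6)
        raw = dry * correction_factor(rh / 100.0, params)
        track = make_track(raw, rh=rh)
        cfg = PreprocessConfig()
        out, report = preprocess_track(track, params, cfg)

        corrected = correct_pm(track, params).data
        pm = corrected["pm25_corrected"].to_numpy()
        lo, hi = np.quantile(pm, [cfg.trim_fraction, 1 - cfg.trim_fraction])
        kept = corrected.loc[(pm >= lo) & (pm <= hi)].reset_index(drop=True)
        med = temporal_median(kept, cfg.median_window)
        local, bg = subtract_background(
            med["pm25_corrected"].to_numpy(), cfg.background_quantile
        )
        assert np.allclose(out["pm25_local"], local)
        assert report["background"] == pytest.approx(bg)
        assert report["n_removed_trim"] == 300 - len(kept)

    def test_rounds_processed_independently(self, small_scene):
        """Preprocessing one round never reads another round."""
        track = small_scene.rounds[0]
        alone, _ = preprocess_track(track)
        again, _ = preprocess_track(track)  # other rounds untouched
        pd.testing.assert_frame_equal(alone, again)

    def test_two_rounds_offset_by_constant_have_identical_local(self, rng):
        dry = rng.uniform(5.0, 30.0, size=300)
        t0 = make_track(dry)
        t1 = make_track(dry + 2.5)
        p0, _ = preprocess_track(t0, CorrectionParams(kappa=0.0))
        p1, _ = preprocess_track(t1, CorrectionParams(kappa=0.0))
        assert np.allclose(p0["pm25_local"], p1["pm25_local"], atol=1e-10)
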