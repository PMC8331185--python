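import numpy as np
import pytest

from pupalyze.errors import (
    DataError,
    DegenerateBaselineError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from pupalyze.signal import (
    PeakTrain,
    Trace,
    bin_epochs,
    build_raster,
    delta_f_over_f,
    detect_peaks,
    moving_average,
    peak_correlation,
)


class TestDeltaFOverF:
    def test_constant_trace_is_all_zero(self):
        out = delta_f_over_f(Trace(np.full(100, 100.0)))
        assert np.allclose(out.values, 0.0)

    @pytest.mark.parametrize("value,expected", [(15.0, 0.5), (5.0, -0.5)])
    def test_baseline_arithmetic(self, value, expected):
        v = np.full(60, 10.0)
        v[55] = value
        out = delta_f_over_f(Trace(v), f0_frames=50)
        assert out.values[55] == pytest.approx(expected)

    def test_zero_baseline_signaled(self):
        with pytest.raises(DegenerateBaselineError):
            delta_f_over_f(Trace(np.zeros(60)))

    def test_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            delta_f_over_f(Trace(np.ones(10)), f0_frames=50)

    def test_invariant_under_gain_scaling(self, rng):
        v = rng.uniform(50, 150, 300)
        a = delta_f_over_f(Trace(v)).values
        b = delta_f_over_f(Trace(3.7 * v)).values
        assert np.allclose(a, b)


class TestMovingAverage:
    def test_constant_and_identity_windows(self):
        v = np.full(200, 5.0)
        assert np.allclose(moving_average(Trace(v)).values, 5.0)
        x = np.arange(50.0)
        assert np.allclose(moving_average(Trace(x), window=1).values, x)

    def test_impulse_plateau_is_height_over_window(self):
        v = np.zeros(500)
        v[250] = 70.0
        out = moving_average(Trace(v), window=100).values
        assert out[250] == pytest.approx(0.7)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            moving_average(Trace(np.ones(10)), window=100)


class TestDetectPeaks:
    def test_flat_trace_has_no_peaks(self):
        assert len(detect_peaks(Trace(np.zeros(300)))) == 0

    def test_single_bump_detected_at_maximum(self):
        v = np.zeros(300)
        v[100:111] = np.concatenate([np.arange(6), np.arange(4, -1, -1)])
        train = detect_peaks(Trace(v), threshold=2.0)
        assert list(train.peak_frames) == [105]

    def test_two_separated_bumps(self):
        v = np.zeros(300)
        for c in (100, 120):
            v[c - 2:c + 3] += [1, 3, 5, 3, 1]
        train = detect_peaks(Trace(v), threshold=2.0, min_separation=5)
        assert list(train.peak_frames) == [100, 120]

    def test_nonfinite_rejected(self):
        v = np.zeros(300)
        v[5] = np.nan
        with pytest.raises(DataError):
            detect_peaks(Trace(v))

    def test_deterministic_rerun(self, rng):
        v = rng.normal(0, 1, 1000) + 5 * (rng.random(1000) < 0.02)
        t1 = detect_peaks(Trace(v))
        t2 = detect_peaks(Trace(v))
        assert np.array_equal(t1.peak_frames, t2.peak_frames)


class TestRaster:
    def test_shapes_and_row_sums(self):
        r = build_raster([PeakTrain([3, 7], label="a"), PeakTrain([], label="b")], 10)
        assert r.matrix.shape == (2, 10)
        assert r.matrix.sum(axis=1).tolist() == [2, 0]
        assert r.rows == ["a", "b"]

    def test_duplicate_peaks_rejected(self):
        with pytest.raises(ValidationError):
            PeakTrain([3, 3, 7])

    def test_out_of_range_peak_rejected(self):
        with pytest.raises(ValidationError):
            build_raster([PeakTrain([12])], 10)


class TestPeakCorrelation:
    def test_identical_trains_correlate_perfectly(self):
        a = PeakTrain([5, 20, 80])
        assert peak_correlation(a, PeakTrain([5, 20, 80]), 100) == pytest.approx(1.0)

    def test_complementary_indicators_anticorrelate(self):
        a = PeakTrain(np.arange(0, 10, 2))
        b = PeakTrain(np.arange(1, 10, 2))
        assert peak_correlation(a, b, 10) == pytest.approx(-1.0)

    def test_constant_indicator_signaled(self):
        with pytest.raises(UndefinedStatisticError):
            peak_correlation(PeakTrain(np.arange(10)), PeakTrain([3]), 10)

    def test_independent_trains_near_zero(self):
        hits = 0
        n_frames, k = 2000, 200
        for seed in range(100):
            g = np.random.default_rng(seed)
            a = PeakTrain(np.sort(g.choice(n_frames, k, replace=False)))
            b = PeakTrain(np.sort(g.choice(n_frames, k, replace=False)))
            hits += abs(peak_correlation(a, b, n_frames)) < 0.1
        assert hits >= 95


class TestBinEpochs:
    def test_event_early_in_span(self):
        out = bin_epochs([10], p0_start=0, p1_onset=100)
        assert list(out.bins["early"]) == [10]

    def test_boundary_goes_to_later_bin(self):
        out = bin_epochs([100], p0_start=0, p1_onset=300)
        assert list(out.bins["mid"]) == [100]

    def test_uniform_events_split_into_equal_tertiles(self):
        out = bin_epochs(np.arange(90), p0_start=0, p1_onset=90)
        assert [len(out.bins[k]) for k in ("early", "mid", "late")] == [30, 30, 30]

    def test_events_after_p1_excluded_and_counted(self):
        out = bin_epochs([10, 150], p0_start=0, p1_onset=100)
        assert out.n_excluded == 1
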