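"""Turbidity preprocessing and regime-detection unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clotlyse.errors import (
    DegenerateTraceError,
    InsufficientWindowError,
    InvalidTraceError,
    NoLysisError,
    NoLysisWarning,
    RegimeDetectionError,
)
from clotlyse.turbidity import (
    NormalizedTrace,
    SlowFit,
    TurbidityTrace,
    compute_timescales,
    detect_cft,
    detect_slow_regime_end,
    detect_tlt,
    fit_slow_regime,
    normalize_trace,
    preprocess,
    read_traces_csv,
    slice_trace,
    smooth_trace,
    write_traces_csv,
)


def make_trace(y, channel="ch0"):
    y = np.asarray(y, dtype=float)
    return TurbidityTrace(np.arange(len(y), dtype=float), y, channel)


class TestTraceValidation:
    def test_rejects_non_increasing_time(self):
        with pytest.raises(InvalidTraceError):
            TurbidityTrace(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_rejects_non_finite_intensity(self):
        with pytest.raises(InvalidTraceError):
            make_trace([1.0, np.nan, 2.0])


class TestSliceTrace:
    @pytest.mark.parametrize(
        "n, keep_every, expected_idx",
        [(9, 3, [0, 3, 6]), (100, 3, None), (12, 1, None)],
    )
    def test_slicing_indices(self, n, keep_every, expected_idx):
        trace = make_trace(np.arange(n, dtype=float))
        out = slice_trace(trace, keep_every)
        if keep_every == 1:
            assert np.array_equal(out.intensity, trace.intensity)
        elif expected_idx is not None:
            assert np.array_equal(out.intensity, np.array(expected_idx, dtype=float))
        else:
            # ceil(100/3) = 34 surviving samples
            assert len(out) == 34

    def test_too_few_survivors_raises(self):
        with pytest.raises(InvalidTraceError):
            slice_trace(make_trace(np.arange(4.0)), 10)


class TestSmoothTrace:
    def test_cubic_polynomial_reproduced_exactly(self):
        """An order-3 filter is exact on cubics (interior samples; the
        mirror-padded boundary sees reflected data, not the polynomial)."""
        t = np.arange(40.0)
        y = 0.01 * t**3 - 0.4 * t**2 + t + 5
        out = smooth_trace(TurbidityTrace(t, y))
        np.testing.assert_allclose(out.intensity[5:-5], y[5:-5], rtol=1e-9)

    def test_constant_signal_unchanged(self):
        out = smooth_trace(make_trace(np.full(20, 7.0)))
        np.testing.assert_allclose(out.intensity, 7.0)

    def test_white_noise_variance_reduced(self):
        reductions = []
        for seed in range(120):
            y = np.random.default_rng(seed).normal(0, 1, 60)
            out = smooth_trace(make_trace(y))
            reductions.append(out.intensity.var() < y.var())
        assert np.mean(reductions) > 0.99

    def test_short_trace_raises(self):
        with pytest.raises(InvalidTraceError):
            smooth_trace(make_trace(np.arange(8.0)))


class TestNormalizeTrace:
    def test_affine_map(self):
        nt = normalize_trace(make_trace([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(nt.nt, [0.0, 0.5, 1.0])
        assert nt.delta_turbidity == pytest.approx(4.0)

    def test_idempotent(self):
        nt = normalize_trace(make_trace([5.0, 1.0, 3.0, 9.0]))
        again = normalize_trace(TurbidityTrace(nt.time, nt.nt))
        np.testing.assert_allclose(again.nt, nt.nt, atol=1e-15)

    def test_delta_turbidity_from_assay_scale(self):
        y = 1000.0 - 700.0 * np.sin(np.linspace(0, np.pi / 2, 30))
        nt = normalize_trace(make_trace(y))
        assert nt.delta_turbidity == pytest.approx(700.0)

    def test_constant_trace_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            normalize_trace(make_trace(np.full(10, 3.0)))


class TestDetectCft:
    def test_v_shape_vertex(self):
        t = np.arange(0.0, 60.0)
        nt = NormalizedTrace(t, np.abs(t - 20.0) / 40.0)
        assert detect_cft(nt) == 20.0

    def test_monotone_increasing_minimum_at_start(self):
        nt = NormalizedTrace(np.arange(30.0), np.linspace(0, 1, 30))
        assert detect_cft(nt) == 0.0

    def test_warns_when_minimum_at_end(self):
        nt = NormalizedTrace(np.arange(30.0), np.linspace(1, 0, 30))
        with pytest.warns(NoLysisWarning):
            detect_cft(nt)


class TestFitSlowRegime:
    def test_exact_line_recovered(self):
        t = np.arange(0.0, 200.0)
        y = np.clip(0.005 * (t - 10.0), 0.0, 1.0)
        fit = fit_slow_regime(NormalizedTrace(t, y))
        assert fit.slope == pytest.approx(0.005, rel=1e-9)
        assert fit.residual_rms < 1e-12

    def test_window_bounds_are_nt_levels(self):
        t = np.arange(0.0, 300.0)
        y = np.clip(0.002 * t, 0.0, 1.0)
        fit = fit_slow_regime(NormalizedTrace(t, y))
        t_lo, t_hi = fit.window
        assert 0.002 * t_lo == pytest.approx(0.01, abs=0.002)
        assert 0.002 * t_hi == pytest.approx(0.075, abs=0.002)

    def test_no_crossing_raises_no_lysis(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(NoLysisError):
            fit_slow_regime(NormalizedTrace(t, np.full(100, 0.02)))

    def test_narrow_window_raises(self):
        # jumps from below 0.01 to above 0.075 within two samples
        y = np.concatenate([np.zeros(10), np.linspace(0.1, 1.0, 30)])
        with pytest.raises(InsufficientWindowError):
            fit_slow_regime(NormalizedTrace(np.arange(40.0), y))


class TestDetectTlt:
    def test_logistic_center_found(self):
        t = np.arange(0.0, 200.0)
        y = 1.0 / (1.0 + np.exp(-0.1 * (t - 120.0)))
        y[:30] = np.linspace(1, 0, 30) * y[30]  # descent so CFT is defined
        nt = NormalizedTrace(t, y)
        cft = detect_cft(nt)
        assert cft + detect_tlt(nt) == pytest.approx(120.0, abs=1.0)

    def test_linear_rise_ties_to_earliest(self):
        # slope 1/64 is binary-exact, so the central-difference derivative is
        # a perfect plateau and the tie must break to the earliest time
        t = np.arange(0.0, 100.0)
        y = np.concatenate([[0.5], np.minimum(np.arange(99.0) * 2.0**-6, 1.0)])
        tlt = detect_tlt(NormalizedTrace(t, y))
        assert tlt == 1.0


class TestDetectSlowRegimeEnd:
    def test_constructed_breakpoint(self):
        t = np.arange(0.0, 200.0)
        slope, t_star = 0.002, 120.0
        y = slope * t + np.where(t > t_star, 0.01 * (t - t_star), 0.0)
        nt = NormalizedTrace(t, np.clip(y, 0, 1))
        fit = SlowFit(slope=slope, intercept=0.0, window=(5.0, 40.0))
        slt = detect_slow_regime_end(nt, fit, tlt=detect_tlt(nt))
        # departure at +0.01/min crosses delta=0.005 half a sample after t*
        assert slt == pytest.approx(t_star, abs=1.0)

    def test_pure_line_never_departs(self):
        t = np.arange(0.0, 150.0)
        y = np.clip(0.004 * t, 0, 1)
        nt = NormalizedTrace(t, y)
        fit = SlowFit(slope=0.004, intercept=0.0, window=(3.0, 20.0))
        tlt = detect_tlt(nt)
        slt = detect_slow_regime_end(nt, fit, tlt=tlt)
        assert slt == pytest.approx(tlt, abs=1.0)

    def test_no_point_near_line_raises(self):
        t = np.arange(0.0, 60.0)
        nt = NormalizedTrace(t, np.clip(0.02 * t, 0, 1))
        fit = SlowFit(slope=0.02, intercept=0.5, window=(1.0, 5.0))  # offset line
        with pytest.raises(RegimeDetectionError):
            detect_slow_regime_end(nt, fit, tlt=30.0)


class TestComputeTimescales:
    def test_regime_ratio_from_published_means(self, clean_assay):
        """SLT 73 min and FLT 67 min give R_SL = 73/140 ≈ 0.521."""
        trace, truth, _ = clean_assay
        ts = compute_timescales(preprocess(trace, 1))
        assert truth.r_sl == pytest.approx(73.0 / 140.0, abs=1e-9)
        assert ts.r_sl == pytest.approx(truth.r_sl, abs=0.02)
        assert ts.r_sl + ts.r_fl == pytest.approx(1.0)

    def test_equal_regimes_split_evenly(self):
        from clotlyse.synthetic import SyntheticAssayConfig, generate_phenomenological

        cfg = SyntheticAssayConfig(slt=60.0, flt=60.0, noise_sd=0.0, n_channels=1)
        traces, _ = generate_phenomenological(cfg)
        ts = compute_timescales(preprocess(traces[0], 1))
        assert ts.r_sl == pytest.approx(0.5, abs=0.02)

    def test_tlt_is_slt_plus_flt(self, clean_assay):
        trace, _, _ = clean_assay
        ts = compute_timescales(preprocess(trace, 1))
        assert ts.tlt == pytest.approx(ts.slt + ts.flt)


class TestAffineInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-500.0, max_value=500.0),
    )
    def test_timescales_invariant_under_intensity_rescaling(self, a, b):
        """The pipeline sees only the normalized signal: x -> a·x + b (a>0)
        must leave every extracted timescale unchanged."""
        from clotlyse.synthetic import SyntheticAssayConfig, generate_phenomenological

        cfg = SyntheticAssayConfig(noise_sd=0.0, n_channels=1)
        trace, _ = generate_phenomenological(cfg)
        trace = trace[0]
        ts0 = compute_timescales(preprocess(trace, 3))
        scaled = TurbidityTrace(trace.time, a * trace.intensity + b)
        ts1 = compute_timescales(preprocess(scaled, 3))
        assert ts1.cft == ts0.cft
        assert ts1.slt == ts0.slt
        assert ts1.tlt == ts0.tlt
        assert ts1.slow_slope == pytest.approx(ts0.slow_slope, rel=1e-9)


class TestCsvRoundTrip:
    def test_long_format_io(self, tmp_path, clean_assay):
        trace, _, _ = clean_assay
        path = tmp_path / "traces.csv"
        write_traces_csv([trace], path)
        back = read_traces_csv(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].intensity, trace.intensity)
        np.testing.assert_allclose(back[0].time, trace.time)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(InvalidTraceError):
            read_traces_csv(p)
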