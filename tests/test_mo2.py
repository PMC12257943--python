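"""Sequential interval regression, linearity filter, background and MMR."""

import numpy as np
import pytest

from irapkit.io_units import PO2Trace
from irapkit.mo2 import correct_background, detect_mmr, fit_mo2_windows

from conftest import make_linear_trace, make_series


class TestWindowFitting:
    def test_constant_po2_gives_zero_mo2(self, config):
        trace = make_linear_trace(slope=0.0)
        series = fit_mo2_windows(trace, config)
        assert all(w.mo2 == 0.0 for w in series.windows)

    def test_linear_decline_matches_single_multiplication_oracle(self, config):
        # 0.01 %sat/s over V_r - V_f = 2.45 L of water holding S_o mg O2/L,
        # per hour, per 0.05 kg: one multiplication, computed independently
        slope = -0.01
        series = fit_mo2_windows(make_linear_trace(slope), config)
        expected = 0.01 * (config.V_r - config.V_f) * config.S_o * 3600.0 / (100.0 * config.M_f)
        assert (config.V_r - config.V_f) == pytest.approx(2.45)
        assert series.windows[0].mo2 == pytest.approx(expected, rel=1e-9)
        assert series.windows[0].r_squared == pytest.approx(1.0)

    def test_window_straddling_kink_has_lower_r2(self, config):
        # perfect two-slope kink: pure windows fit exactly, straddlers do not
        n, kink = 60, 30
        t = np.arange(n, dtype=float)
        po2 = np.where(t < kink, 100.0 - 0.01 * t, 100.0 - 0.01 * kink - 0.05 * (t - kink))
        trace = PO2Trace("c", t, po2, np.full(n, 18.0), np.full(n, "measurement", dtype=object))
        series = fit_mo2_windows(trace, config, window_s=20.0, stride="rolling")
        r2 = {w.start_index: w.r_squared for w in series.windows}
        pure_left = r2[0]
        pure_right = r2[n - 21]
        straddling = r2[kink - 10]
        assert straddling < pure_left and straddling < pure_right
        assert pure_left == pytest.approx(1.0) and pure_right == pytest.approx(1.0)

    def test_sequential_windows_subset_of_rolling(self, config):
        rng = np.random.default_rng(3)
        n = 50
        t = np.arange(n, dtype=float)
        po2 = 100.0 - 0.02 * t + rng.normal(0, 0.05, n)
        trace = PO2Trace("c", t, po2, np.full(n, 18.0), np.full(n, "measurement", dtype=object))
        seq = fit_mo2_windows(trace, config, window_s=10.0, stride="sequential")
        roll = fit_mo2_windows(trace, config, window_s=10.0, stride="rolling")
        roll_by_start = {w.start_index: w for w in roll.windows}
        for w in seq.windows:
            assert w.start_index in roll_by_start
            assert roll_by_start[w.start_index].mo2 == pytest.approx(w.mo2, rel=1e-12)

    def test_mo2_invariant_to_time_shift_and_po2_offset(self, config):
        base = fit_mo2_windows(make_linear_trace(-0.01), config)
        shifted = make_linear_trace(-0.01)
        shifted.time_s = shifted.time_s + 5000.0
        shifted.po2 = shifted.po2 - 20.0
        other = fit_mo2_windows(shifted, config)
        assert other.windows[0].mo2 == pytest.approx(base.windows[0].mo2, rel=1e-12)

    def test_halving_mass_doubles_mass_specific_mo2(self, config):
        light = config.model_copy(update={"M_f": config.M_f / 2})
        heavy = fit_mo2_windows(make_linear_trace(-0.01), config)
        lighter = fit_mo2_windows(make_linear_trace(-0.01), light)
        assert lighter.windows[0].mo2 == pytest.approx(2 * heavy.windows[0].mo2, rel=1e-12)

    def test_trace_without_measurement_phase_rejected(self, config):
        with pytest.raises(ValueError, match="measurement"):
            fit_mo2_windows(make_linear_trace(0.0, phase="flush"), config)


class TestBackground:
    def test_zero_blank_leaves_series_unchanged(self, config):
        series = make_series([100.0, 110.0], [60.0, 120.0], config)
        blank = make_series([0.0, 0.0], [60.0, 120.0], config)
        out = correct_background(series, blank)
        assert [w.mo2 for w in out.windows] == [100.0, 110.0]
        assert out.background_corrected

    def test_constant_blank_subtracts_exactly(self, config):
        series = make_series([100.0, 110.0, 120.0], [60.0, 120.0, 180.0], config)
        blank = make_series([4.0, 4.0, 4.0], [60.0, 120.0, 180.0], config)
        out = correct_background(series, blank)
        assert [w.mo2 for w in out.windows] == [96.0, 106.0, 116.0]

    def test_high_background_warns(self, config):
        series = make_series([100.0], [60.0], config)
        blank = make_series([8.0], [60.0], config)
        with pytest.warns(UserWarning, match="5%"):
            correct_background(series, blank)

    def test_no_temporal_overlap_rejected(self, config):
        series = make_series([100.0], [60.0], config)
        blank = make_series([4.0], [9000.0], config)
        with pytest.raises(ValueError, match="overlap"):
            correct_background(series, blank)


class TestMMR:
    def test_monotone_decay_peaks_in_first_cycle(self, config):
        vals = [400.0, 350.0, 300.0, 250.0]
        series = make_series(vals, [120.0, 300.0, 480.0, 660.0], config)
        mmr, at = detect_mmr(series)
        assert mmr == 400.0
        assert at == 120.0

    def test_single_window_series(self, config):
        series = make_series([123.0], [60.0], config)
        assert detect_mmr(series)[0] == 123.0

    def test_tie_breaks_toward_earlier_time(self, config):
        series = make_series([400.0, 400.0, 100.0], [120.0, 300.0, 480.0], config)
        assert detect_mmr(series)[1] == 120.0

    def test_all_excluded_raises_helpful_error(self, config):
        series = make_series([400.0], [120.0], config, excluded=[True])
        with pytest.raises(ValueError, match="window length"):
            detect_mmr(series)
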