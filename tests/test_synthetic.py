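"""Simulator contracts: determinism, closed-form slopes, ramp arithmetic."""

import numpy as np
import pytest

from irapkit.mo2 import fit_mo2_windows
from irapkit.synthetic import (
    CycleProtocol,
    TrialTruth,
    default_config,
    simulate_cardiac_trial,
    simulate_hypoxia_phase,
    simulate_irap_trial,
    simulate_tolerance_ramp,
)

SHORT = CycleProtocol(total_duration_s=3600.0, recovery_duration_s=3600.0)


def test_same_seed_identical_traces_different_seed_differ(config):
    t1, b1, _ = simulate_irap_trial(config, TrialTruth(seed=7), SHORT)
    t2, _, _ = simulate_irap_trial(config, TrialTruth(seed=7), SHORT)
    t3, _, _ = simulate_irap_trial(config, TrialTruth(seed=8), SHORT)
    np.testing.assert_array_equal(t1.po2, t2.po2)
    assert not np.array_equal(t1.po2, t3.po2)
    assert b1.is_blank


def test_constant_mo2_gives_identical_measurement_slopes(config):
    # no noise, no recovery decay, no diel cycle -> every slope equal
    truth = TrialTruth(seed=0, noise_sd=0.0, recovery_k=1e-9, diel_amplitude=0.0)
    trace, _, _ = simulate_irap_trial(config, truth, SHORT)
    series = fit_mo2_windows(trace, config)
    slopes = np.array([w.slope for w in series.windows])
    assert slopes.size >= 5
    np.testing.assert_allclose(slopes, slopes[0], rtol=1e-6)


def test_first_recovery_window_slope_matches_closed_form(config):
    truth = TrialTruth(
        seed=0, noise_sd=0.0, recovery_k=1e-9, diel_amplitude=0.0, background_rate=0.0
    )
    trace, _, _ = simulate_irap_trial(config, truth, SHORT)
    series = fit_mo2_windows(trace, config)
    # closed-form decline for a constant uptake of mmr_true in a sealed chamber
    expected = (
        truth.mmr_true * config.M_f * 100.0 / (config.S_o * (config.V_r - config.V_f) * 3600.0)
    )
    assert abs(series.windows[0].slope) == pytest.approx(expected, rel=1e-6)


def test_hypoxia_phase_regulation_plateau_flat(config):
    truth = TrialTruth(seed=0, noise_sd=0.0)
    trace = simulate_hypoxia_phase(config, truth)
    series = fit_mo2_windows(trace, config)
    above = [w for w in series.windows if w.mean_po2 > truth.pcrit_true * 1.2]
    mo2 = np.array([w.mo2 for w in above])
    assert mo2.size >= 5
    # oxyregulation: uptake independent of PO2 above P_crit
    np.testing.assert_allclose(mo2, mo2.mean(), rtol=2e-2)


def test_hypoxia_phase_gives_ten_points_before_conformity(config, truth):
    trace = simulate_hypoxia_phase(config, truth)
    series = fit_mo2_windows(trace, config)
    wins = sorted(series.windows, key=lambda w: -w.mean_po2)
    n_before = 0
    for w in wins:
        if w.mo2 < truth.smr_true:
            break
        n_before += 1
    assert n_before >= 10


def test_contradictory_hypoxia_truth_rejected():
    with pytest.raises(ValueError):
        TrialTruth(pcrit_true=5.0, loehyp_true=8.0)


class TestToleranceRamps:
    def test_thermal_ramp_arithmetic(self):
        # 18 -> 30 degC at 0.1 degC/min means LOE at 120 min
        truth = TrialTruth(ctmax_true=30.0)
        ramp = simulate_tolerance_ramp("thermal", truth, thermal_start_c=18.0)
        assert ramp.loe_time_s == pytest.approx(120.0 * 60.0, abs=1.0)
        assert ramp.driver[-1] == pytest.approx(30.0, abs=1e-6)

    def test_hypoxia_ramp_ends_at_true_endpoint(self):
        truth = TrialTruth(loehyp_true=5.0)
        ramp = simulate_tolerance_ramp("hypoxia", truth)
        assert ramp.driver[-1] == pytest.approx(5.0, abs=1e-3)
        assert ramp.mode == "hypoxia"

    def test_doubling_rate_halves_time_but_not_endpoint(self):
        truth = TrialTruth(ctmax_true=30.0)
        slow = simulate_tolerance_ramp("thermal", truth, thermal_rate_c_per_min=0.1)
        fast = simulate_tolerance_ramp("thermal", truth, thermal_rate_c_per_min=0.2)
        assert fast.loe_time_s == pytest.approx(slow.loe_time_s / 2, abs=2.0)
        assert fast.driver[-1] == pytest.approx(slow.driver[-1], abs=1e-2)

    def test_endpoint_outside_ramp_rejected(self):
        with pytest.raises(ValueError):
            simulate_tolerance_ramp("thermal", TrialTruth(ctmax_true=10.0), thermal_start_c=18.0)


class TestCardiacTrial:
    def test_flat_curve_when_q10_is_one(self):
        truth = TrialTruth(q10_true=1.0, tpeak_true=28.0, tarr_true=29.0)
        beats = simulate_cardiac_trial(truth, rr_jitter_cv=0.0)
        rr = np.diff(beats.beat_times_s)
        # before arrhythmia onset every RR is identical
        pre = rr[beats.beat_times_s[1:] < 360.0 * (29.0 - 12.0)]
        np.testing.assert_allclose(pre, pre[0], rtol=1e-9)

    def test_schedule_must_start_at_12(self):
        with pytest.raises(ValueError):
            simulate_cardiac_trial(TrialTruth(), schedule=[(0.0, 14.0), (360.0, 15.0)])

    def test_inconsistent_peak_and_arrhythmia_rejected(self):
        with pytest.raises(ValueError):
            TrialTruth(tpeak_true=28.0, tarr_true=25.0)
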