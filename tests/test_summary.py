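"""SMR quantile, EPOC integration and mass-centred means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irapkit.summary import compute_epoc, estimate_smr, mass_adjusted_means

from conftest import make_series

H = 3600.0


class TestSMR:
    def test_constant_series_returns_that_value(self, config):
        times = [13 * H + k * 600 for k in range(10)]
        series = make_series([50.0] * 10, times, config)
        smr, n = estimate_smr(series)
        assert smr == 50.0
        assert n == 10

    def test_quantile_matches_hand_interpolation(self, config):
        # {1..10}: zero-based position 0.2*(10-1)=1.8 -> 2 + 0.8*(3-2) = 2.8
        times = [13 * H + k * 600 for k in range(10)]
        series = make_series(list(range(1, 11)), times, config)
        smr, _ = estimate_smr(series)
        assert smr == pytest.approx(2.8, rel=1e-12)

    def test_first_hours_excluded(self, config):
        # early windows (recovery) carry huge values; they must not enter
        times = [1 * H, 2 * H, 13 * H, 14 * H, 15 * H]
        series = make_series([400.0, 300.0, 50.0, 50.0, 50.0], times, config)
        smr, n = estimate_smr(series)
        assert smr == 50.0
        assert n == 3

    def test_empty_after_trim_rejected(self, config):
        series = make_series([100.0], [60.0], config)
        with pytest.raises(ValueError):
            estimate_smr(series)

    @given(perm_seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_permutation_of_values(self, config, perm_seed):
        rng = np.random.default_rng(perm_seed)
        vals = rng.uniform(40, 120, 30)
        times = [13 * H + k * 600 for k in range(30)]
        base, _ = estimate_smr(make_series(vals, times, config))
        shuffled, _ = estimate_smr(make_series(rng.permutation(vals), times, config))
        assert shuffled == pytest.approx(base, rel=1e-12)


class TestEPOC:
    def test_series_at_smr_gives_zero(self, config):
        series = make_series([50.0] * 5, [60.0, 120.0, 180.0, 240.0, 300.0], config)
        with pytest.warns(UserWarning):
            epoc, _ = compute_epoc(series, smr=50.0)
        assert epoc == 0.0

    def test_threshold_semantics_stop_at_third_window(self, config):
        # third window dips to <= 1.1*smr: integrate exactly the first two
        smr = 100.0
        vals = [300.0, 200.0, 105.0, 300.0]
        times = [H, 2 * H, 3 * H, 4 * H]
        series = make_series(vals, times, config)
        epoc, end = compute_epoc(series, smr)
        # midpoint boundaries give each window a 1-h footprint
        assert epoc == pytest.approx((300 - 100) * 1.0 + (200 - 100) * 1.0, rel=1e-9)
        assert end == 3 * H

    def test_exponential_recovery_matches_analytic_integral(self, config):
        # mo2(t) = smr + (mmr-smr) e^{-kt}; excess integral to the 1.1*smr
        # crossing is ((mmr-smr) - 0.1 smr)/k
        smr, mmr, k = 90.0, 450.0, 1.5
        t = np.arange(0.025, 6.0, 0.05)  # dense half-cycle midpoints (h)
        mo2 = smr + (mmr - smr) * np.exp(-k * t)
        series = make_series(mo2, t * H, config)
        epoc, _ = compute_epoc(series, smr)
        analytic = ((mmr - smr) - 0.1 * smr) / k
        assert epoc == pytest.approx(analytic, rel=0.01)

    @given(f1=st.floats(1.05, 1.3), f2=st.floats(0.0, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold_factor(self, config, f1, f2):
        t = np.arange(0.5, 5.0, 0.25)
        mo2 = 90.0 + 360.0 * np.exp(-1.5 * t)
        series = make_series(mo2, t * H, config)
        lo, _ = compute_epoc(series, 90.0, threshold_factor=f1)
        hi, _ = compute_epoc(series, 90.0, threshold_factor=f1 + f2)
        assert lo >= hi - 1e-9  # larger threshold stops earlier -> smaller EPOC

    def test_unit_weighting_option(self, config):
        series = make_series([300.0, 110.0], [H, 2 * H], config)
        epoc, _ = compute_epoc(series, 100.0, duration_weighted=False)
        assert epoc == pytest.approx(200.0)


class TestMassAdjustedMeans:
    def test_known_allometry_recovered(self):
        # values = A_g * mass^b exactly; refit must recover b and offsets
        rng = np.random.default_rng(0)
        b = 0.85
        masses = np.concatenate([rng.uniform(0.02, 0.1, 12), rng.uniform(0.02, 0.1, 12)])
        groups = np.array(["lo"] * 12 + ["hi"] * 12)
        A = np.where(groups == "lo", 200.0, 260.0)
        values = A * masses**b
        out = mass_adjusted_means(values, masses, groups, common_mass_kg=0.05)
        assert out["allometric_slope"].iloc[0] == pytest.approx(b, abs=1e-9)
        adj = dict(zip(out["group"], out["adjusted_mean"]))
        assert adj["hi"] / adj["lo"] == pytest.approx(260.0 / 200.0, rel=1e-6)
        assert adj["lo"] == pytest.approx(200.0 * 0.05**b, rel=1e-6)

    def test_equal_masses_reduce_to_geometric_means(self):
        values = np.array([10.0, 40.0, 20.0, 80.0])
        masses = np.full(4, 0.05)
        groups = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="slope"):
            out = mass_adjusted_means(values, masses, groups)
        adj = dict(zip(out["group"], out["adjusted_mean"]))
        assert adj["a"] == pytest.approx(20.0, rel=1e-9)  # sqrt(10*40)
        assert adj["b"] == pytest.approx(40.0, rel=1e-9)  # sqrt(20*80)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            mass_adjusted_means(
                np.array([1.0, 2.0]), np.array([0.1, 0.2]), np.array(["a", "a"])
            )
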