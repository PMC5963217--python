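"""Steady-state inversion vs the forward ODE oracle, and full-station inversion."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dlamino import synthetic
from dlamino.profiles_io import ModelConstants
from dlamino.racemization import k_asp
from dlamino.turnover import (
    BelowLiveRatioError,
    NearEquilibriumError,
    forward_necromass,
    invert_station,
    tb_from_tnm,
    tnm_steady_state,
)

DL_LIVE = 0.014
F_LIVE = DL_LIVE / (1 + DL_LIVE)


class TestSteadyStateInversion:
    def test_hot_anchor_pair(self):
        # printed deepest hot-station pair: D:L 0.481 at 65.51 degC -> ~4 yr
        t_nm = tnm_steady_state(0.481 / 1.481, 0.2218, DL_LIVE)
        assert t_nm == pytest.approx(4.0, rel=2e-3)

    def test_fresh_necromass_limit(self):
        assert tnm_steady_state(F_LIVE + 1e-9, 0.1, DL_LIVE) < 1e-6

    def test_equilibrium_limit_diverges(self):
        assert tnm_steady_state(0.4999999, 0.1, DL_LIVE) > 1e5

    def test_below_live_ratio_raises(self):
        with pytest.raises(BelowLiveRatioError):
            tnm_steady_state(0.005, 0.1, DL_LIVE)

    def test_at_equilibrium_raises(self):
        with pytest.raises(NearEquilibriumError):
            tnm_steady_state(0.5, 0.1, DL_LIVE)

    def test_strictly_increasing_in_d(self):
        ds = np.linspace(F_LIVE + 1e-4, 0.499, 60)
        ts = [tnm_steady_state(d, 0.01, DL_LIVE) for d in ds]
        assert np.all(np.diff(ts) > 0)

    def test_strictly_decreasing_in_k(self):
        ks = np.logspace(-5, 0, 40)
        ts = [tnm_steady_state(0.2, k, DL_LIVE) for k in ks]
        assert np.all(np.diff(ts) < 0)

    def test_log_tnm_linear_in_inverse_kelvin_at_fixed_d(self, calib):
        temps = np.array([10.0, 40.0, 70.0])
        inv_tk = 1.0 / (temps + 273.15)
        log_t = np.log([tnm_steady_state(0.2, k_asp(t, calib), DL_LIVE) for t in temps])
        s01 = (log_t[1] - log_t[0]) / (inv_tk[1] - inv_tk[0])
        s12 = (log_t[2] - log_t[1]) / (inv_tk[2] - inv_tk[1])
        assert s01 == pytest.approx(s12, rel=1e-9)


class TestForwardOracle:
    def test_round_trip_on_random_parameter_triples(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            t_nm = float(10 ** rng.uniform(-1, 4))
            k = float(10 ** rng.uniform(-5, 0))
            dl_live = float(rng.uniform(0.005, 0.05))
            d = forward_necromass(t_nm, k, dl_live)
            worst = max(worst, abs(tnm_steady_state(d, k, dl_live) - t_nm) / t_nm)
        assert worst < 1e-3

    def test_fast_turnover_limit_returns_live_fraction(self):
        d = forward_necromass(1e-9, 0.1, DL_LIVE)
        assert d == pytest.approx(F_LIVE, abs=1e-9)

    def test_no_racemization_returns_live_fraction_exactly(self):
        assert forward_necromass(100.0, 0.0, DL_LIVE) == pytest.approx(F_LIVE, abs=1e-12)

    def test_printed_pair_forward(self):
        d = forward_necromass(4.0, 0.2218, DL_LIVE)
        assert d == pytest.approx(0.3248, abs=5e-4)

    def test_pool_conserved_at_flux_times_turnover(self):
        # the steady pool equals F * T_NM = total_asp by construction; d must
        # be independent of the pool size
        d_small = forward_necromass(50.0, 0.01, DL_LIVE, total_asp=0.01)
        d_large = forward_necromass(50.0, 0.01, DL_LIVE, total_asp=100.0)
        assert d_small == pytest.approx(d_large, rel=1e-9)

    def test_nonconvergence_within_horizon_raises(self):
        with pytest.raises(RuntimeError, match="steady state"):
            forward_necromass(1000.0, 1e-4, DL_LIVE, horizon=1.0)


class TestBiomassTurnover:
    def test_equal_pools_equal_times(self):
        assert tb_from_tnm(4.0, 2.0, 2.0) == 4.0

    def test_zero_biomass_zero_turnover(self):
        assert tb_from_tnm(4.0, 0.0, 2.0) == 0.0

    def test_small_pool_ratio_gives_days(self):
        # pool ratio 6.85e-4 of 4 yr is ~1 day
        t_b = tb_from_tnm(4.0, 6.85e-4, 1.0)
        assert t_b * 365.25 == pytest.approx(1.0, rel=2e-3)

    def test_linear_in_biomass(self):
        assert tb_from_tnm(10.0, 3.0, 5.0) == 3 * tb_from_tnm(10.0, 1.0, 5.0)

    def test_zero_necromass_rejected(self):
        with pytest.raises(ValueError):
            tb_from_tnm(4.0, 1.0, 0.0)


class TestInvertStation:
    def test_noise_free_round_trip_recovers_true_tnm(self, constants, calib):
        template = synthetic.default_configs()["SO241-51"]
        meta, horizons, _ = synthetic.generate_station(template, constants, calib)
        results = invert_station(meta, horizons, calib, constants)
        assert len(results) == template.n_horizons
        for r, true in zip(results, template.true_tnm):
            assert abs(r.t_nm - true) / true < 1e-3
            assert r.t_b <= r.t_nm  # biomass pool far smaller than necromass

    def test_below_live_ratio_flagged_not_fatal(self, constants, calib, hot_station):
        from dlamino.profiles_io import GeochemSample, Horizon, IsomerMeasurement

        horizons = [
            Horizon(
                sample=GeochemSample(depth=48.0),
                isomers=IsomerMeasurement(d_asp=5.0, l_asp=995.0, hydrolysis_corrected=True),
            ),
            Horizon(
                sample=GeochemSample(depth=98.0),
                isomers=IsomerMeasurement(d_asp=100.0, l_asp=900.0, hydrolysis_corrected=True),
            ),
        ]
        results = invert_station(hot_station, horizons, calib, constants)
        assert "below_live_ratio" in results[0].flags
        assert math.isnan(results[0].t_nm)
        assert results[1].flags == frozenset()
        assert math.isfinite(results[1].t_nm)

    def test_noisy_recovery_median_error_under_15_percent(self, constants, calib):
        template = replace(synthetic.default_configs()["SO241-58"], noise_sigma=0.05, seed=11)
        meta, horizons, _ = synthetic.generate_station(template, constants, calib)
        results = invert_station(meta, horizons, calib, constants)
        errors = [
            abs(r.t_nm - true) / true
            for r, true in zip(results, template.true_tnm)
            if math.isfinite(r.t_nm)
        ]
        assert len(errors) >= 8
        assert np.median(errors) < 0.15
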