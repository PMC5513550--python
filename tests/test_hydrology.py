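import numpy as np
import pytest

from ecoclim.climate_io import N_WEEKS
from ecoclim.hydrology import (IrrigationScenario, apply_irrigation, bucket_step,
                               potential_evapotranspiration, run_bucket,
                               summer_weeks)


class TestIrrigation:
    def test_southern_summer_week_topped_up(self):
        precip = np.full(N_WEEKS, 2.0)
        out = apply_irrigation(precip, lat=-42.0, scen=IrrigationScenario(rate=2.5))
        assert out[0] == pytest.approx(17.5)        # January week
        assert out[26] == pytest.approx(2.0)        # July week: out of season

    def test_already_wet_week_unchanged(self):
        precip = np.full(N_WEEKS, 30.0)
        out = apply_irrigation(precip, lat=-42.0, scen=IrrigationScenario(rate=2.5))
        assert np.array_equal(out, precip)

    def test_output_never_below_input(self):
        rng = np.random.default_rng(0)
        for lat in (-42.0, 0.0, 42.0):
            precip = rng.uniform(0, 40, N_WEEKS)
            out = apply_irrigation(precip, lat, IrrigationScenario(rate=2.5))
            assert np.all(out >= precip)

    def test_hemisphere_seasons_complementary(self):
        north, south = summer_weeks(45.0), summer_weeks(-45.0)
        assert north.sum() == 27 and south.sum() == 25
        assert not (north & south).any()
        assert summer_weeks(0.5)[17]   # equator follows the northern convention

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            IrrigationScenario(rate=-1.0)

    def test_none_scenario_is_identity(self):
        precip = np.full(N_WEEKS, 2.0)
        assert np.array_equal(apply_irrigation(precip, -42.0, None), precip)


class TestEvapotranspiration:
    def test_no_demand_below_freezing(self):
        assert potential_evapotranspiration(np.array([-5.0]), np.array([0.5]))[0] == 0

    def test_saturated_air_no_demand(self):
        assert potential_evapotranspiration(np.array([20.0]), np.array([1.0]))[0] == 0

    def test_reference_value(self):
        ep = potential_evapotranspiration(np.array([20.0]), np.array([0.5]), k_et=0.6)
        assert ep[0] == pytest.approx(42.0)  # 7 * 0.6 * 20 * 0.5

    def test_decreasing_in_humidity(self):
        rh = np.linspace(0, 1, 11)
        ep = potential_evapotranspiration(np.full(11, 20.0), rh)
        assert np.all(np.diff(ep) < 0)

    def test_invalid_humidity_rejected(self):
        with pytest.raises(ValueError, match="humidity"):
            potential_evapotranspiration(np.array([20.0]), np.array([1.2]))


class TestBucket:
    def test_no_flux_fixed_point(self):
        zeros = np.zeros(N_WEEKS)
        res = run_bucket(zeros, zeros, sm_init=0.5)
        assert np.allclose(res.sm, 0.5)

    def test_single_step_arithmetic(self):
        sm, ea = bucket_step(sm_prev=0.5, precip=35.0, et_potential=14.0, capacity=100.0)
        assert ea == pytest.approx(7.0)      # 14 * min(1, 0.5)
        assert sm == pytest.approx(0.78)     # 0.5 + (35 - 7) / 100

    def test_dry_year_decays_to_zero(self):
        res = run_bucket(np.zeros(N_WEEKS), np.full(N_WEEKS, 10.0), sm_init=1.0)
        assert res.sm[-1] == pytest.approx(0.0, abs=1e-5)
        # independent brute-force: iterate the recurrence directly
        sm = 1.0
        for _ in range(200 * N_WEEKS):
            sm = max(sm - 10.0 * min(1.0, sm) / 100.0, 0.0)
        assert res.sm[-1] == pytest.approx(sm, abs=1e-5)

    def test_monotone_in_precipitation(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ep = rng.uniform(0, 30, N_WEEKS)
            p_lo = rng.uniform(0, 20, N_WEEKS)
            p_hi = p_lo + rng.uniform(0, 10, N_WEEKS)
            sm_lo = run_bucket(p_lo, ep).sm
            sm_hi = run_bucket(p_hi, ep).sm
            assert np.all(sm_hi >= sm_lo - 1e-9)

    def test_spinup_independent_of_initial_store(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            p = rng.uniform(0, 30, N_WEEKS)
            ep = rng.uniform(0, 30, N_WEEKS)
            base = run_bucket(p, ep, sm_init=0.0).sm
            for sm0 in rng.uniform(0, 5, 3):
                assert np.allclose(run_bucket(p, ep, sm_init=sm0).sm, base, atol=1e-4)

    def test_store_bounded(self):
        res = run_bucket(np.full(N_WEEKS, 200.0), np.zeros(N_WEEKS), sm_cap=5.0)
        assert res.sm.max() <= 5.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            run_bucket(np.full(N_WEEKS, -1.0), np.zeros(N_WEEKS))
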