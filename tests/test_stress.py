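import numpy as np
import pytest

from ecoclim.climate_io import N_WEEKS
from ecoclim.params import preset
from ecoclim.stress import (StressResult, accumulate, cold_stress, combine,
                            compute_stresses, consecutive_weeks, dry_stress,
                            heat_stress, hot_wet_stress, wet_stress)


def accumulate_oracle(exc, rate):
    """Brute-force re-derivation of the persistence-weighted accumulation.

    Run counts computed on the doubled series so runs wrap across the year
    boundary; an all-year run keeps its plain cumulative count.
    """
    exc = np.asarray(exc, dtype=float)
    active = exc > 0
    n = np.zeros(N_WEEKS)
    if active.all():
        n = np.arange(1, N_WEEKS + 1, dtype=float)
    else:
        doubled = np.concatenate([active, active])
        for w in range(N_WEEKS):
            k = 0
            i = N_WEEKS + w
            while k < N_WEEKS and doubled[i - k]:
                k += 1
            n[w] = k
    return 100.0 * min(1.0, abs(rate) * float(np.sum(exc * n)))


class TestAccumulate:
    def test_no_exceedance_no_stress(self):
        assert accumulate(np.zeros(N_WEEKS), 0.5) == 0.0

    def test_capped_at_100(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            assert accumulate(rng.uniform(0, 50, N_WEEKS), 0.5) <= 100.0

    def test_all_year_uses_cumulative_week_count(self):
        # sum_w 0.008 * 0.1 * w = 0.0008 * 1378 > 1 -> capped
        assert accumulate(np.full(N_WEEKS, 0.1), 0.008) == 100.0

    def test_run_counts_wrap_over_new_year(self):
        active = np.zeros(N_WEEKS, dtype=bool)
        active[-3:] = True   # weeks 50-52
        active[:3] = True    # weeks 1-3
        n = consecutive_weeks(active)
        assert list(n[-3:]) == [1, 2, 3]
        assert list(n[:3]) == [4, 5, 6]
        assert n[3] == 0

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            exc = rng.uniform(0, 1, N_WEEKS) * (rng.random(N_WEEKS) < 0.4)
            rate = rng.uniform(0, 0.05)
            assert accumulate(exc, rate) == pytest.approx(
                accumulate_oracle(exc, rate))

    def test_monotone_in_exceedance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            lo = rng.uniform(0, 1, N_WEEKS) * (rng.random(N_WEEKS) < 0.5)
            hi = lo + rng.uniform(0, 0.5, N_WEEKS)
            rate = rng.uniform(0, 0.02)
            assert accumulate(hi, rate) >= accumulate(lo, rate)


class TestColdStress:
    def test_warm_year_no_stress(self, current):
        dd_cs = np.full(N_WEEKS, 7 * (20 - 6.5))   # 94.5 >> DTCS = 10
        assert cold_stress(dd_cs, current) == 0.0

    def test_cold_year_saturates(self, current):
        # at the developmental threshold all year: shortfall 10 every week
        assert cold_stress(np.zeros(N_WEEKS), current) == 100.0

    def test_boundary_is_stress_free(self, current):
        assert cold_stress(np.full(N_WEEKS, 10.0), current) == 0.0


class TestHeatStress:
    def test_at_threshold_no_stress(self, current):
        assert heat_stress(np.full(N_WEEKS, 33.0), current) == 0.0

    def test_above_threshold_saturates(self, current):
        assert heat_stress(np.full(N_WEEKS, 35.0), current) == 100.0

    def test_cool_year_no_stress(self, current):
        assert heat_stress(np.full(N_WEEKS, 20.0), current) == 0.0


class TestDryStress:
    def test_moist_year_no_stress(self, current):
        assert dry_stress(np.full(N_WEEKS, 0.25), current) == 0.0

    def test_at_threshold_no_stress(self, current):
        assert dry_stress(np.full(N_WEEKS, 0.2), current) == 0.0

    def test_dry_year_saturates(self, current):
        assert dry_stress(np.full(N_WEEKS, 0.1), current) == 100.0


class TestWetStress:
    def test_disabled_in_current_model(self, current):
        assert wet_stress(np.full(N_WEEKS, 4.0), current) == 0.0

    def test_boundary_is_stress_free(self, spradbery):
        assert wet_stress(np.full(N_WEEKS, 2.5), spradbery) == 0.0

    def test_saturates_above_threshold(self, spradbery):
        assert wet_stress(np.full(N_WEEKS, 3.0), spradbery) == 100.0


class TestHotWetStress:
    def test_requires_both_legs(self, current):
        assert hot_wet_stress(np.full(N_WEEKS, 20.0), np.full(N_WEEKS, 2.0),
                              current) == 0.0
        assert hot_wet_stress(np.full(N_WEEKS, 25.0), np.full(N_WEEKS, 0.3),
                              current) == 0.0

    def test_joint_condition_saturates(self, current):
        assert hot_wet_stress(np.full(N_WEEKS, 25.0), np.full(N_WEEKS, 0.6),
                              current) == 100.0

    def test_absent_mechanism_is_inert(self):
        p = preset("tribe_richardson")
        assert hot_wet_stress(np.full(N_WEEKS, 30.0), np.full(N_WEEKS, 3.0), p) == 0.0


class TestCombine:
    def test_stress_free_factor_is_one(self):
        assert combine(StressResult()) == 1.0

    def test_any_total_stress_zeroes_the_factor(self):
        assert combine(StressResult(dry=100.0)) == 0.0

    def test_product_form(self):
        assert combine(StressResult(cold=50.0, dry=50.0)) == pytest.approx(0.25)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine(StressResult(cold=120.0))


def test_interaction_stresses_inactive_under_all_presets():
    rng = np.random.default_rng(4)
    tavg = rng.uniform(-10, 40, N_WEEKS)
    sm = rng.uniform(0, 4, N_WEEKS)
    dd_cs = rng.uniform(0, 100, N_WEEKS)
    for name in ("spradbery_maywald", "tribe_richardson", "sutherst", "current"):
        s = compute_stresses(tavg, sm, dd_cs, preset(name))
        assert s.cold_dry == s.cold_wet == s.hot_dry == 0.0
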