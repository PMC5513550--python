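"""Synthetic monthly climate normals for contrasting climate archetypes.

Real applications of the model run on gridded long-term normals (CliMond)
and a global irrigation map; neither ships with this package.  This module
generates tables with the same structure for five contrasting archetypes,
so that every pipeline stage can be exercised end to end:

``patagonia_xeric``
    Southern-hemisphere cold steppe: < 250 mm/year falling mostly in
    winter, mild summers, cold winters.  Calibrated so that under natural
    rainfall the soil stays too dry for any growth (the growing-season
    store sits below the lower moisture threshold 0.2), while the 2.5
    mm/day summer top-up produces a growth pulse peaking in austral late
    summer — the seasonal-phenology situation of the Patagonian steppe.
``mediterranean``
    Winter-wet, summer-dry mid-latitude climate (annual mean cycle ≈ 8–24 °C).
``tropical_hot_wet``
    Hot (all months > 24 °C), very wet (> 1800 mm/year), humid (> 0.7).
``alpine_cold``
    All months below 6 °C.
``optimal_constant``
    A diagnostic climate: constant 22 °C and precipitation tuned so the
    spun-up soil moisture sits in the optimal band all year; the pipeline
    must score it EI = 100.

Monthly temperature follows a sinusoidal annual cycle (peak late January /
July by hemisphere); precipitation seasonality is a cosine weighting over
months.  All randomness flows through one seeded generator; profile
contracts are verified after generation and generation is retried with
fresh jitter (bounded) if a contract fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .climate_io import LocationClimate
from .hydrology import IrrigationScenario
from .params import preset

__all__ = ["PROFILE_NAMES", "make_site", "make_grid"]

PROFILE_NAMES = (
    "patagonia_xeric",
    "mediterranean",
    "tropical_hot_wet",
    "alpine_cold",
    "optimal_constant",
)

_MAX_RETRIES = 10


def _annual_temp_cycle(mean: float, amp: float, peak_month: float) -> np.ndarray:
    """Monthly mean temperature: sinusoid peaking at ``peak_month`` (0-based)."""
    m = np.arange(12)
    return mean + amp * np.cos(2.0 * np.pi * (m - peak_month) / 12.0)


def _seasonal_precip(annual: float, concentration: float, peak_month: float) -> np.ndarray:
    """Monthly precipitation summing to ``annual``, cosine-weighted seasonality."""
    m = np.arange(12)
    w = 1.0 + concentration * np.cos(2.0 * np.pi * (m - peak_month) / 12.0)
    w = np.maximum(w, 0.0)
    return annual * w / w.sum()


@dataclass(frozen=True)
class _ProfileSpec:
    lat_range: Tuple[float, float]
    lon_range: Tuple[float, float]
    tmean: float
    tamp: float
    dtr: float              # diurnal range: tmax - tmin
    annual_precip: float
    precip_conc: float      # cosine concentration of precipitation
    precip_peak: str        # "winter" | "summer" | "none"
    rh_mean: float
    rh_seasonal: float      # cosine amplitude of monthly RH
    jitter_t: float         # uniform jitter half-width on tmean
    jitter_p: float         # relative jitter half-width on annual precip
    # phase offsets in months relative to the hemisphere's default
    # late-summer temperature peak; rh phase marks the *driest* month
    t_peak_offset: float = 0.0
    rh_peak_offset: float = 0.0


_SPECS = {
    # Cold dry steppe; sparse winter-peaked precipitation and very dry,
    # windy late-spring air so the store is drained before growth starts.
    "patagonia_xeric": _ProfileSpec(
        lat_range=(-45.0, -40.0), lon_range=(-71.5, -68.0),
        tmean=9.4, tamp=10.3, dtr=12.0,
        annual_precip=52.0, precip_conc=0.5, precip_peak="winter",
        rh_mean=0.55, rh_seasonal=0.25,
        jitter_t=0.5, jitter_p=0.08,
        t_peak_offset=-0.4, rh_peak_offset=-3.0,
    ),
    "mediterranean": _ProfileSpec(
        lat_range=(-34.5, -33.0), lon_range=(18.0, 22.0),
        tmean=16.0, tamp=8.0, dtr=10.0,
        annual_precip=550.0, precip_conc=0.85, precip_peak="winter",
        rh_mean=0.60, rh_seasonal=0.08,
        jitter_t=0.4, jitter_p=0.06,
    ),
    "tropical_hot_wet": _ProfileSpec(
        lat_range=(2.0, 8.0), lon_range=(98.0, 112.0),
        tmean=26.5, tamp=1.0, dtr=8.0,
        annual_precip=2300.0, precip_conc=0.3, precip_peak="summer",
        rh_mean=0.82, rh_seasonal=0.03,
        jitter_t=0.4, jitter_p=0.05,
    ),
    "alpine_cold": _ProfileSpec(
        lat_range=(-33.5, -32.0), lon_range=(-70.5, -69.5),
        tmean=0.0, tamp=5.0, dtr=10.0,
        annual_precip=600.0, precip_conc=0.5, precip_peak="winter",
        rh_mean=0.60, rh_seasonal=0.05,
        jitter_t=0.3, jitter_p=0.05,
    ),
    # Diagnostic profile: deliberately constant; only coordinates jitter.
    "optimal_constant": _ProfileSpec(
        lat_range=(-35.0, -30.0), lon_range=(140.0, 150.0),
        tmean=22.0, tamp=0.0, dtr=10.0,
        annual_precip=26.0 * 52.0, precip_conc=0.0, precip_peak="none",
        rh_mean=0.70, rh_seasonal=0.0,
        jitter_t=0.0, jitter_p=0.0,
    ),
}


def _build_site(profile: str, spec: _ProfileSpec, rng: np.random.Generator,
                attempt: int) -> LocationClimate:
    lat = float(rng.uniform(*spec.lat_range))
    lon = float(rng.uniform(*spec.lon_range))
    south = lat < 0
    # temperature peaks in late summer: early Feb (S) / late Jul (N)
    base_peak = 1.0 if south else 6.5
    t_peak = base_peak + spec.t_peak_offset
    rh_peak = base_peak + spec.rh_peak_offset
    winter_peak = (t_peak + 6.0) % 12.0
    tmean = spec.tmean + rng.uniform(-spec.jitter_t, spec.jitter_t)
    tavg = _annual_temp_cycle(tmean, spec.tamp, t_peak)
    tmin = tavg - spec.dtr / 2.0
    tmax = tavg + spec.dtr / 2.0

    annual_p = spec.annual_precip * (1.0 + rng.uniform(-spec.jitter_p, spec.jitter_p))
    if spec.precip_peak == "winter":
        p_peak = winter_peak
        conc = spec.precip_conc
    elif spec.precip_peak == "summer":
        p_peak = t_peak
        conc = spec.precip_conc
    else:
        p_peak, conc = 0.0, 0.0
    precip = _seasonal_precip(annual_p, conc, p_peak)

    # RH cycle with its driest month at rh_peak
    rh = spec.rh_mean - spec.rh_seasonal * np.cos(
        2.0 * np.pi * (np.arange(12) - rh_peak) / 12.0
    )
    rh09 = np.clip(rh + 0.05, 0.0, 1.0)
    rh15 = np.clip(rh - 0.05, 0.0, 1.0)

    return LocationClimate(
        site_id=f"{profile}_{attempt}",
        lat=lat, lon=lon,
        tmin=tmin, tmax=tmax, precip=precip, rh09=rh09, rh15=rh15,
    )


def _check_contract(profile: str, site: LocationClimate) -> str | None:
    """Return a violation message, or None if the profile contract holds."""
    tavg = site.tavg
    south = site.lat < 0
    summer = np.array([0, 1, 11]) if south else np.array([5, 6, 7])
    winter = np.array([5, 6, 7]) if south else np.array([0, 1, 11])
    if profile == "patagonia_xeric":
        if not south:
            return "hemisphere: lat must be southern"
        if site.precip.sum() >= 250:
            return "annual precipitation must be < 250 mm"
        if site.precip[winter].sum() <= site.precip[summer].sum():
            return "precipitation must be concentrated in winter"
        st = tavg[summer].mean()
        if not 12.0 <= st <= 22.0:
            return f"summer tavg {st:.1f} outside [12, 22]"
        if tavg[winter].mean() >= 5.0:
            return "winter tavg must be < 5 °C"
        # growing-season store must stay below the lower moisture threshold
        from .pipeline import run_weekly

        series = run_weekly(site, preset("current"), None)
        growing = series.ti > 0
        if growing.any() and series.sm[growing].max() >= 0.2:
            return "natural-rainfall growing-season soil moisture must stay below 0.2"
        irr = run_weekly(site, preset("current"), IrrigationScenario())
        if irr.gi.max() <= 0:
            return "summer top-up irrigation must enable growth"
        peak = 1 + int(np.argmax(irr.gi))
        if not 9 <= peak <= 13:
            return f"irrigated growth must peak in austral late summer, got week {peak}"
    elif profile == "tropical_hot_wet":
        if tavg.min() <= 24.0:
            return "all-month tavg must exceed 24 °C"
        if site.precip.sum() <= 1800:
            return "annual precipitation must exceed 1800 mm"
        if 0.5 * (site.rh09 + site.rh15).min() <= 0.7:
            return "relative humidity must exceed 0.7"
    elif profile == "alpine_cold":
        if tavg.max() >= 6.0:
            return "all-month tavg must be below 6 °C"
    elif profile == "mediterranean":
        if site.precip[winter].sum() <= 2.0 * site.precip[summer].sum():
            return "winter precipitation must dominate"
        if not (6.0 <= tavg.min() <= 12.0 and 20.0 <= tavg.max() <= 26.0):
            return "annual tavg cycle must span roughly 8-24 °C"
    elif profile == "optimal_constant":
        from .hydrology import potential_evapotranspiration, run_bucket
        from .pipeline import run_weekly
        from .climate_io import monthly_to_weekly

        wk = monthly_to_weekly(site)
        sm = run_bucket(wk.precip,
                        potential_evapotranspiration(wk.tavg, wk.rh)).sm
        if not (sm.min() >= 0.8 and sm.max() <= 1.2):
            return "spun-up soil moisture must lie in [0.8, 1.2]"
    else:
        return f"unknown profile {profile!r}"
    return None


def make_site(profile: str, seed: int) -> LocationClimate:
    """Generate one site for a named archetype; deterministic in (profile, seed)."""
    if profile not in _SPECS:
        raise ValueError(
            f"unknown profile {profile!r}; valid profiles: {', '.join(PROFILE_NAMES)}"
        )
    spec = _SPECS[profile]
    idx = PROFILE_NAMES.index(profile)
    last = ""
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng([seed, idx, attempt])
        site = _build_site(profile, spec, rng, attempt)
        violation = _check_contract(profile, site)
        if violation is None:
            site.site_id = f"{profile}_{seed}"
            return site
        last = violation
    raise RuntimeError(
        f"profile {profile!r} contract unsatisfiable after {_MAX_RETRIES} retries: {last}"
    )


def make_grid(nrow: int, ncol: int, seed: int
              ) -> Tuple[List[LocationClimate], np.ndarray]:
    """Synthetic grid: cold-to-hot with latitude, arid-to-wet with longitude.

    Rows run from high southern latitude (cold) at row 0 to the equator
    (hot) at the last row; columns run from hyper-arid in the west to
    tropical-wet in the east.  The irrigation mask is a contiguous patch
    in the temperate part of the arid sector, emulating irrigated
    agriculture inside a desert.  Returns (cells row-major, mask).
    """
    if nrow <= 0 or ncol <= 0:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng([seed, 10_007])
    lats = np.linspace(-48.0, -2.0, nrow)
    lons = np.linspace(-75.0, -55.0, ncol)
    frac_lat = (lats - lats.min()) / (lats.max() - lats.min() + 1e-12)
    frac_lon = (lons - lons.min()) / (lons.max() - lons.min() + 1e-12)
    cells: List[LocationClimate] = []
    for i in range(nrow):
        # mean temperature 4 °C at the cold edge up to 27 °C at the equator,
        # seasonal amplitude shrinking toward the tropics
        tmean = 4.0 + 23.0 * frac_lat[i]
        tamp = 10.0 * (1.0 - frac_lat[i]) + 1.0
        for j in range(ncol):
            annual_p = 120.0 + (2400.0 - 120.0) * frac_lon[j] ** 2
            rh = 0.35 + 0.45 * frac_lon[j]
            tavg = _annual_temp_cycle(tmean + rng.uniform(-0.3, 0.3), tamp, 1.0)
            precip = _seasonal_precip(annual_p * (1 + rng.uniform(-0.05, 0.05)),
                                      0.4, 7.0)
            rh_m = np.clip(np.full(12, rh) + rng.uniform(-0.02, 0.02), 0.0, 1.0)
            cells.append(LocationClimate(
                site_id=f"cell_{i}_{j}", lat=float(lats[i]), lon=float(lons[j]),
                tmin=tavg - 6.0, tmax=tavg + 6.0, precip=precip,
                rh09=np.clip(rh_m + 0.05, 0, 1), rh15=np.clip(rh_m - 0.05, 0, 1),
                row=i, col=j,
            ))
    mask = np.zeros(nrow * ncol, dtype=bool)
    # contiguous irrigated patch: temperate rows, arid (western) third
    r0, r1 = nrow // 4, max(nrow // 4 + 1, nrow // 2)
    c1 = max(1, ncol // 3)
    for i in range(r0, r1):
        mask[i * ncol: i * ncol + c1] = True
    return cells, mask


def default_scenario() -> IrrigationScenario:
    """The 2.5 mm/day summer top-up scenario."""
    return IrrigationScenario(rate=2.5, season="summer", mode="top_up")
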