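"""Weekly soil-moisture bucket model and the summer top-up irrigation scenario.

Soil moisture follows a 100 mm single-bucket model expressed as a
dimensionless store (0 = oven dry, 1 = field capacity).  Each week the
bucket receives effective precipitation (natural rainfall, optionally
topped up by irrigation) and loses actual evapotranspiration; the store is
clamped to [0, sm_cap] with excess above sm_cap discarded as runoff.
Values above 1 represent supersaturation, so that high wet-stress
thresholds (e.g. 2.5) are reachable.

The evaporative-demand term is an explicit stand-in — a temperature- and
humidity-driven linear rate ``Ep = 7 * k_et * max(0, tavg) * (1 - rh)``
(mm/week) — because the engine needs a demand term and nothing more
elaborate is warranted by monthly normals.  ``k_et`` is exposed so the
sensitivity of results to this choice can be probed.

The irrigation scenario raises weekly rainfall to at least ``7 * rate``
mm/week during the local summer half-year ("top-up": already-wet weeks
are unchanged).  The default rate is 2.5 mm/day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_io import N_WEEKS

__all__ = [
    "IrrigationScenario",
    "SoilMoistureSeries",
    "summer_weeks",
    "apply_irrigation",
    "potential_evapotranspiration",
    "bucket_step",
    "run_bucket",
]

#: default bucket capacity, mm
CAPACITY_MM = 100.0
#: default ET coefficient, mm / day / °C
K_ET = 0.6
#: default supersaturation ceiling (dimensionless store)
SM_CAP = 5.0


@dataclass(frozen=True)
class IrrigationScenario:
    """Summer top-up irrigation: weekly rainfall floored at ``7 * rate`` in summer."""

    rate: float = 2.5         # mm/day
    season: str = "summer"    # {"summer", "none"}
    mode: str = "top_up"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"irrigation rate must be non-negative, got {self.rate}")
        if self.season not in ("summer", "none"):
            raise ValueError(f"unknown irrigation season {self.season!r}")
        if self.mode != "top_up":
            raise ValueError(f"unknown irrigation mode {self.mode!r}")


@dataclass
class SoilMoistureSeries:
    """Spun-up weekly soil-moisture trajectory with its water fluxes."""

    sm: np.ndarray                 # dimensionless store, 1 = field capacity
    effective_precip: np.ndarray   # mm/week
    et: np.ndarray                 # actual evapotranspiration, mm/week


def summer_weeks(lat: float) -> np.ndarray:
    """Boolean mask (52,) of the local summer half-year.

    Northern hemisphere: weeks 18–44 (≈ May–Oct); southern: weeks 1–17 and
    45–52 (≈ Nov–Apr).  Sites within 1° of the equator follow the northern
    convention.  Weeks are 1-based in this description; the mask is 0-based.
    """
    weeks = np.arange(1, N_WEEKS + 1)
    if lat >= -1.0:
        return (weeks >= 18) & (weeks <= 44)
    return (weeks <= 17) | (weeks >= 45)


def apply_irrigation(precip: np.ndarray, lat: float,
                     scen: IrrigationScenario | None) -> np.ndarray:
    """Apply the summer top-up scenario to weekly rainfall (mm/week).

    In-season weeks are raised to at least ``7 * scen.rate``; out-of-season
    weeks pass through.  Output is pointwise >= input.
    """
    precip = np.asarray(precip, dtype=float)
    if precip.shape != (N_WEEKS,):
        raise ValueError(f"precip must have {N_WEEKS} weekly values")
    if scen is None or scen.season == "none" or scen.rate == 0:
        return precip.copy()
    floor = 7.0 * scen.rate
    out = precip.copy()
    mask = summer_weeks(lat)
    out[mask] = np.maximum(out[mask], floor)
    return out


def potential_evapotranspiration(tavg: np.ndarray, rh: np.ndarray,
                                 k_et: float = K_ET) -> np.ndarray:
    """Weekly evaporative demand Ep = 7 * k_et * max(0, tavg) * (1 - rh), mm/week."""
    tavg = np.asarray(tavg, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 1)):
        raise ValueError("relative humidity outside [0, 1]")
    return 7.0 * k_et * np.maximum(0.0, tavg) * (1.0 - rh)


def bucket_step(sm_prev: float, precip: float, et_potential: float,
                capacity: float = CAPACITY_MM, sm_cap: float = SM_CAP) -> tuple[float, float]:
    """One weekly bucket update; returns (sm, actual_et).

    Actual evapotranspiration is soil-limited: ``Ea = Ep * min(1, sm_prev)``;
    the store moves by ``(P - Ea) / capacity`` and is clamped to [0, sm_cap].
    """
    ea = et_potential * min(1.0, sm_prev)
    sm = min(max(sm_prev + (precip - ea) / capacity, 0.0), sm_cap)
    return sm, ea


def run_bucket(effective_precip: np.ndarray, et_potential: np.ndarray,
               capacity: float = CAPACITY_MM, sm_init: float = 0.0,
               sm_cap: float = SM_CAP, spinup_tol: float = 1e-6,
               spinup_max_cycles: int = 100) -> SoilMoistureSeries:
    """Run the weekly bucket to its annually periodic steady state.

    The weekly update is ``sm_w = clamp(sm_{w-1} + (P_w - Ea_w) / capacity,
    0, sm_cap)`` with soil-limited actual evapotranspiration
    ``Ea_w = Ep_w * min(1, sm_{w-1})``.  The year is cycled with
    carried-over final moisture until the trajectory changes by less than
    ``spinup_tol`` (uniform norm), so the reported series is independent of
    ``sm_init``.
    """
    p = np.asarray(effective_precip, dtype=float)
    ep = np.asarray(et_potential, dtype=float)
    if p.shape != (N_WEEKS,) or ep.shape != (N_WEEKS,):
        raise ValueError(f"inputs must have {N_WEEKS} weekly values")
    if capacity <= 0:
        raise ValueError("bucket capacity must be positive")
    if np.any(p < 0) or np.any(ep < 0):
        raise ValueError("precipitation and evaporative demand must be non-negative")

    sm_prev_cycle = None
    sm = float(np.clip(sm_init, 0.0, sm_cap))
    series = np.empty(N_WEEKS)
    ea = np.empty(N_WEEKS)
    for _ in range(spinup_max_cycles):
        for w in range(N_WEEKS):
            sm, ea[w] = bucket_step(sm, p[w], ep[w], capacity, sm_cap)
            series[w] = sm
        if sm_prev_cycle is not None and np.max(np.abs(series - sm_prev_cycle)) < spinup_tol:
            return SoilMoistureSeries(sm=series.copy(), effective_precip=p.copy(), et=ea.copy())
        sm_prev_cycle = series.copy()
    raise RuntimeError(
        f"soil-moisture spin-up did not converge within {spinup_max_cycles} cycles"
    )
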