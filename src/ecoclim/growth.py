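"""Weekly temperature/moisture response indices, growth indices and degree-days.

The temperature index TI_W and moisture index MI_W are piecewise-linear
trapezoids over (DV0, DV1, DV2, DV3) and (SM0, SM1, SM2, SM3): zero at or
below the lower threshold, rising linearly to 1 at the lower optimum,
flat at 1 across the optimal band, falling linearly to zero at the upper
threshold.  The weekly growth index is their product GI_W = TI_W * MI_W
and the annual growth index GI_A = 100 * mean(GI_W).

TI_W is computed from the weekly mean temperature (tavg); no diurnal-cycle
integration is attempted (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_io import N_WEEKS
from .params import ParameterSet

__all__ = [
    "WeeklySeries",
    "trapezoid",
    "temperature_index",
    "moisture_index",
    "weekly_growth_index",
    "annual_growth_index",
    "degree_days",
    "weekly_degree_days",
]


@dataclass
class WeeklySeries:
    """Weekly response and growth indices plus degree-day series."""

    ti: np.ndarray     # temperature index, [0, 1]
    mi: np.ndarray     # moisture index, [0, 1]
    gi: np.ndarray     # growth index = ti * mi
    dd: np.ndarray     # °C-days/week above DV0
    dd_cs: np.ndarray  # °C-days/week above DVCS (cold-stress leg)


def trapezoid(x, lo: float, opt_lo: float, opt_hi: float, hi: float):
    """Trapezoidal membership: 0 below ``lo``, 1 on [opt_lo, opt_hi], 0 above ``hi``.

    Thresholds are closed at zero: the function is exactly 0 at ``lo`` and
    ``hi``.  Degenerate (zero-width) ramps fall back to step edges.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if opt_lo > lo:
        rising = (x > lo) & (x < opt_lo)
        out[rising] = (x[rising] - lo) / (opt_lo - lo)
    inside = (x >= opt_lo) & (x <= opt_hi)
    out[inside] = 1.0
    if hi > opt_hi:
        falling = (x > opt_hi) & (x < hi)
        out[falling] = (hi - x[falling]) / (hi - opt_hi)
    # x == lo or x == hi stay 0; x <= lo and x >= hi stay 0
    out[(x <= lo) | (x >= hi)] = 0.0
    return out if out.ndim else float(out)


def temperature_index(tavg, p: ParameterSet):
    """Weekly temperature response TI_W over (DV0, DV1, DV2, DV3)."""
    return trapezoid(tavg, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(sm, p: ParameterSet):
    """Weekly moisture response MI_W over (SM0, SM1, SM2, SM3)."""
    return trapezoid(sm, p.SM0, p.SM1, p.SM2, p.SM3)


def weekly_growth_index(ti, mi):
    """GI_W = TI_W * MI_W."""
    ti = np.asarray(ti, dtype=float)
    mi = np.asarray(mi, dtype=float)
    out = ti * mi
    return out if out.ndim else float(out)


def annual_growth_index(gi: np.ndarray) -> float:
    """GI_A = 100 * mean of the 52 weekly growth indices, in [0, 100]."""
    gi = np.asarray(gi, dtype=float)
    if gi.shape != (N_WEEKS,):
        raise ValueError(f"gi must have {N_WEEKS} weekly values")
    return 100.0 * float(np.mean(gi))


def weekly_degree_days(tavg: np.ndarray, threshold: float) -> np.ndarray:
    """°C-days accumulated each week above ``threshold``: 7 * max(0, tavg - threshold)."""
    tavg = np.asarray(tavg, dtype=float)
    return 7.0 * np.maximum(0.0, tavg - threshold)


def degree_days(tavg: np.ndarray, threshold: float) -> float:
    """Annual degree-day total above ``threshold`` over the 52-week year."""
    tavg = np.asarray(tavg, dtype=float)
    if tavg.shape != (N_WEEKS,):
        raise ValueError(f"tavg must have {N_WEEKS} weekly values")
    return float(np.sum(weekly_degree_days(tavg, threshold)))
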