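"""Annual stress indices: cold, heat, dry, wet and hot-wet.

Each stress mechanism turns a weekly exceedance series (how far the
climate sits beyond its threshold, 0 where the condition is not met) into
an annual index on [0, 100].  Accumulation compounds with persistence:
with ``n_w`` the number of consecutive stressed weeks ending at week ``w``
(runs wrap across the Dec->Jan boundary so southern-hemisphere summers are
not split),

    stress = 100 * min(1, sum_w |rate| * exceedance_w * n_w)

so a condition that persists accrues stress faster than one that flickers.
When the condition holds all 52 weeks the run count is the plain cumulative
week number (no wrap extension: the year is a single unbroken run).

Thresholds are strict: a week sitting exactly on its threshold accrues no
stress, so each published threshold is exactly the zero-stress supremum.

The cold-dry, cold-wet and hot-dry interaction stresses are structurally
present in :class:`StressResult` but carry no parameters in any preset and
are always zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_io import N_WEEKS
from .params import ParameterSet

__all__ = [
    "StressResult",
    "accumulate",
    "consecutive_weeks",
    "cold_stress",
    "heat_stress",
    "dry_stress",
    "wet_stress",
    "hot_wet_stress",
    "compute_stresses",
    "combine",
]


@dataclass(frozen=True)
class StressResult:
    """Annual stress indices (each 0–100) and their multiplicative survivor factor."""

    cold: float = 0.0
    heat: float = 0.0
    dry: float = 0.0
    wet: float = 0.0
    hot_wet: float = 0.0
    # interaction stresses: representable but unparameterised, always 0
    cold_dry: float = 0.0
    cold_wet: float = 0.0
    hot_dry: float = 0.0

    @property
    def combined_factor(self) -> float:
        """Product of (1 - S/100) over all stresses, in [0, 1]."""
        return combine(self)

    def as_tuple(self):
        return (self.cold, self.heat, self.dry, self.wet, self.hot_wet,
                self.cold_dry, self.cold_wet, self.hot_dry)


def consecutive_weeks(active: np.ndarray) -> np.ndarray:
    """Run length of consecutive True weeks ending at each week, with Dec->Jan wrap.

    If every week is active the year is one unbroken run and the count is
    simply 1..52; otherwise a run in progress at week 52 extends the run
    that starts at week 1.
    """
    active = np.asarray(active, dtype=bool)
    if active.shape != (N_WEEKS,):
        raise ValueError(f"active must have {N_WEEKS} weekly values")
    n = np.zeros(N_WEEKS, dtype=float)
    run = 0
    for w in range(N_WEEKS):
        run = run + 1 if active[w] else 0
        n[w] = run
    if active[0] and active[-1] and not active.all():
        tail = 0
        w = N_WEEKS - 1
        while active[w]:
            tail += 1
            w -= 1
        w = 0
        while active[w]:
            n[w] += tail
            w += 1
    return n


def accumulate(exceedance: np.ndarray, rate: float) -> float:
    """Annual stress (0–100) from a weekly exceedance series and a rate (week^-1)."""
    exc = np.asarray(exceedance, dtype=float)
    if exc.shape != (N_WEEKS,):
        raise ValueError(f"exceedance must have {N_WEEKS} weekly values")
    if np.any(exc < 0):
        raise ValueError("exceedance must be non-negative")
    n = consecutive_weeks(exc > 0)
    total = abs(rate) * float(np.sum(exc * n))
    return 100.0 * min(1.0, total)


def cold_stress(dd_cs: np.ndarray, p: ParameterSet) -> float:
    """Cold stress from weekly degree-days above DVCS: shortfall below DTCS accrues."""
    dd_cs = np.asarray(dd_cs, dtype=float)
    exc = np.maximum(0.0, p.DTCS - dd_cs)
    return accumulate(exc, p.DHCS)


def heat_stress(tavg: np.ndarray, p: ParameterSet) -> float:
    """Heat stress: weekly mean temperature above TTHS accrues at THHS."""
    tavg = np.asarray(tavg, dtype=float)
    exc = np.maximum(0.0, tavg - p.TTHS)
    return accumulate(exc, p.THHS)


def dry_stress(sm: np.ndarray, p: ParameterSet) -> float:
    """Dry stress: soil moisture below SMDS accrues at |HDS|."""
    sm = np.asarray(sm, dtype=float)
    exc = np.maximum(0.0, p.SMDS - sm)
    return accumulate(exc, p.HDS)


def wet_stress(sm: np.ndarray, p: ParameterSet) -> float:
    """Wet stress: soil moisture above SMWS accrues at HWS; a zero rate disables it."""
    if p.HWS == 0:
        return 0.0
    sm = np.asarray(sm, dtype=float)
    exc = np.maximum(0.0, sm - p.SMWS)
    return accumulate(exc, p.HWS)


def hot_wet_stress(tavg: np.ndarray, sm: np.ndarray, p: ParameterSet) -> float:
    """Hot-wet stress: binary joint condition (tavg > TTHW and sm > MTHW) at PHW.

    The joint indicator (not a product of exceedance magnitudes) is used:
    the mechanism stands in for biotic pressures that build with the
    duration of hot-wet conditions rather than their intensity.
    """
    if p.PHW == 0:
        return 0.0
    tavg = np.asarray(tavg, dtype=float)
    sm = np.asarray(sm, dtype=float)
    cond = (tavg > p.TTHW) & (sm > p.MTHW)
    return accumulate(cond.astype(float), p.PHW)


def compute_stresses(tavg: np.ndarray, sm: np.ndarray, dd_cs: np.ndarray,
                     p: ParameterSet) -> StressResult:
    """Evaluate all five active stress mechanisms for one spun-up year."""
    return StressResult(
        cold=cold_stress(dd_cs, p),
        heat=heat_stress(tavg, p),
        dry=dry_stress(sm, p),
        wet=wet_stress(sm, p),
        hot_wet=hot_wet_stress(tavg, sm, p),
    )


def combine(s: StressResult) -> float:
    """Multiplicative survivor factor: product of (1 - S/100) over all stresses."""
    factor = 1.0
    for v in s.as_tuple():
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"stress index outside [0, 100]: {v}")
        factor *= 1.0 - v / 100.0
    return factor
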