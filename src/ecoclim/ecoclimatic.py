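"""The Ecoclimatic Index (EI) and its suitability classification.

EI combines annual growth potential with annual stresses and a
generation-length gate:

    EI = GI_A * prod(1 - S_i/100)   if annual degree-days >= PDD, else 0

EI ranges 0–100.  Suitability classes follow the conventional scheme:
unsuitable EI = 0; marginal 1–4; suitable 5–9; highly suitable 10–29;
optimal 30–100, applied to EI rounded half-up to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ParameterSet
from .stress import StressResult

__all__ = [
    "AnnualIndices",
    "ecoclimatic_index",
    "classify_ei",
    "is_suitable",
    "EI_CLASSES",
]

EI_CLASSES = ("unsuitable", "marginal", "suitable", "highly_suitable", "optimal")


@dataclass(frozen=True)
class AnnualIndices:
    """Annual model outputs for one location under one scenario."""

    gi_a: float                 # annual growth index, 0-100
    stresses: StressResult
    dd_annual: float            # degree-days above DV0
    ei: float                   # ecoclimatic index, 0-100
    ei_class: str


def ecoclimatic_index(gi_a: float, stresses: StressResult, dd_annual: float,
                      p: ParameterSet) -> float:
    """EI = GI_A * combined stress factor, gated to 0 when dd_annual < PDD."""
    if not 0.0 <= gi_a <= 100.0:
        raise ValueError(f"gi_a outside [0, 100]: {gi_a}")
    if dd_annual < p.PDD:
        return 0.0
    return gi_a * stresses.combined_factor


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def classify_ei(ei: float) -> str:
    """Suitability class from EI (rounded half-up to integer)."""
    if not 0.0 <= ei <= 100.0:
        raise ValueError(f"EI outside [0, 100]: {ei}")
    k = _round_half_up(ei)
    if k == 0:
        return "unsuitable"
    if k <= 4:
        return "marginal"
    if k <= 9:
        return "suitable"
    if k <= 29:
        return "highly_suitable"
    return "optimal"


def is_suitable(ei: float) -> bool:
    """True iff EI rounds to at least 1 (the conventional presence criterion)."""
    if not 0.0 <= ei <= 100.0:
        raise ValueError(f"EI outside [0, 100]: {ei}")
    return _round_half_up(ei) >= 1
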