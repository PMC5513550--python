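"""Parameter sets for the *Vespula germanica* ecoclimatic niche model.

A :class:`ParameterSet` holds every threshold and rate used by the model:
the temperature and soil-moisture response trapezoids (``DV0..DV3``,
``SM0..SM3``), the five active stress mechanisms (cold, heat, dry, wet,
hot-wet) and the annual degree-day requirement ``PDD``.

Four published parameterisations of the species are shipped as named
presets (:func:`preset`): the original Spradbery & Maywald model, the
Tribe & Richardson model, the Sutherst revision, and the current model
that lowers the developmental threshold to 6.5 °C, disables wet stress and
re-tunes hot-wet stress.

Stress accumulation rates are stored with their published sign (cold and
dry rates are negative, meaning stress accrues as conditions fall *below*
the threshold); the stress engine uses absolute magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = ["ParameterSet", "preset", "PRESET_NAMES", "read_params", "write_params"]

#: Symbol order used by the config file format and validation messages.
PARAM_KEYS = (
    "DV0", "DV1", "DV2", "DV3",
    "SM0", "SM1", "SM2", "SM3",
    "DTCS", "DHCS", "DVCS",
    "TTHS", "THHS",
    "SMDS", "HDS",
    "SMWS", "HWS",
    "TTHW", "MTHW", "PHW",
    "PDD",
)


@dataclass(frozen=True)
class ParameterSet:
    """All model parameters for one variant.

    Attributes
    ----------
    DV0, DV1, DV2, DV3:
        Temperature response thresholds (°C): zero below DV0, optimal on
        [DV1, DV2], zero above DV3.
    SM0, SM1, SM2, SM3:
        Soil-moisture response thresholds (dimensionless; 1 = field
        capacity of the 100 mm single-bucket soil moisture model).
    DTCS:
        Cold-stress degree-day threshold (°C-days/week): stress
        accumulates in weeks with fewer degree-days above DVCS than this.
    DHCS:
        Cold-stress accumulation rate (week^-1, stored negative).
    DVCS:
        Cold-stress developmental temperature threshold (°C).
    TTHS, THHS:
        Heat-stress temperature threshold (°C) and rate (week^-1).
    SMDS, HDS:
        Dry-stress soil-moisture threshold and rate (week^-1, negative).
    SMWS, HWS:
        Wet-stress soil-moisture threshold and rate (week^-1); a zero
        rate disables the mechanism.
    TTHW, MTHW, PHW:
        Hot-wet stress temperature threshold (°C), moisture threshold and
        rate (week^-1); stress accrues in weeks that are jointly hot and
        wet.
    PDD:
        Degree-days above DV0 required to complete one generation per
        year; locations below it are unsuitable.
    """

    DV0: float
    DV1: float
    DV2: float
    DV3: float
    SM0: float
    SM1: float
    SM2: float
    SM3: float
    DTCS: float
    DHCS: float
    DVCS: float
    TTHS: float
    THHS: float
    SMDS: float
    HDS: float
    SMWS: float
    HWS: float
    TTHW: float
    MTHW: float
    PHW: float
    PDD: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (self.DV0 <= self.DV1 <= self.DV2 <= self.DV3):
            raise ValueError(
                "temperature thresholds must satisfy DV0 <= DV1 <= DV2 <= DV3, "
                f"got ({self.DV0}, {self.DV1}, {self.DV2}, {self.DV3})"
            )
        if not (self.SM0 <= self.SM1 <= self.SM2 <= self.SM3):
            raise ValueError(
                "moisture thresholds must satisfy SM0 <= SM1 <= SM2 <= SM3, "
                f"got ({self.SM0}, {self.SM1}, {self.SM2}, {self.SM3})"
            )
        if self.PDD < 0:
            raise ValueError(f"PDD must be non-negative, got {self.PDD}")
        for key in PARAM_KEYS:
            v = getattr(self, key)
            if not math.isfinite(v):
                raise ValueError(f"parameter {key} is not finite: {v}")

    def to_dict(self) -> dict:
        """Flat symbol -> value mapping (plus ``name``)."""
        d = {k: getattr(self, k) for k in PARAM_KEYS}
        d["name"] = self.name
        return d


_PRESETS = {
    "spradbery_maywald": ParameterSet(
        DV0=10, DV1=18, DV2=26, DV3=33,
        SM0=0, SM1=0.6, SM2=1.5, SM3=2.5,
        DTCS=10, DHCS=-0.00014, DVCS=10,
        TTHS=31, THHS=0.0035,
        SMDS=0.2, HDS=-0.006,
        SMWS=2.5, HWS=0.002,
        TTHW=26, MTHW=0.8, PHW=0.03,
        PDD=350, name="spradbery_maywald",
    ),
    "tribe_richardson": ParameterSet(
        DV0=10, DV1=18, DV2=26, DV3=31,
        SM0=0.2, SM1=0.8, SM2=2, SM3=3,
        DTCS=10, DHCS=-0.00014, DVCS=10,
        TTHS=30, THHS=0.005,
        SMDS=0.2, HDS=-0.01,
        SMWS=3, HWS=0.002,
        # this variant carries no hot-wet stress mechanism
        TTHW=0, MTHW=0, PHW=0,
        PDD=350, name="tribe_richardson",
    ),
    "sutherst": ParameterSet(
        DV0=10, DV1=18, DV2=26, DV3=31,
        SM0=0.2, SM1=0.6, SM2=1.5, SM3=2.5,
        DTCS=10, DHCS=-0.00014, DVCS=10,
        TTHS=31, THHS=0.0035,
        SMDS=0.15, HDS=-0.008,
        SMWS=2.5, HWS=0.002,
        TTHW=26, MTHW=0.8, PHW=0.03,
        PDD=350, name="sutherst",
    ),
    "current": ParameterSet(
        DV0=6.5, DV1=18, DV2=26, DV3=33,
        SM0=0.2, SM1=0.6, SM2=1.5, SM3=2.5,
        DTCS=10, DHCS=-0.00016, DVCS=6.5,
        TTHS=33, THHS=0.0035,
        SMDS=0.2, HDS=-0.008,
        # wet stress disabled: zero rate means the mechanism is off
        SMWS=0, HWS=0,
        TTHW=22, MTHW=0.4, PHW=0.009,
        PDD=350, name="current",
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> ParameterSet:
    """Return one of the four published parameterisations by name.

    Parameters
    ----------
    name:
        One of ``spradbery_maywald``, ``tribe_richardson``, ``sutherst``
        or ``current``.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


def write_params(p: ParameterSet, path: Union[str, Path]) -> None:
    """Write a parameter set as a flat YAML ``key: value`` file."""
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)


def read_params(path: Union[str, Path]) -> ParameterSet:
    """Read a parameter file written by :func:`write_params`.

    Every symbol must be present; unknown keys are rejected so that typos
    never silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} does not contain a mapping")
    name = raw.pop("name", "custom")
    missing = [k for k in PARAM_KEYS if k not in raw]
    if missing:
        raise ValueError(f"parameter file {path} missing keys: {', '.join(missing)}")
    extra = [k for k in raw if k not in PARAM_KEYS]
    if extra:
        raise ValueError(f"parameter file {path} has unknown keys: {', '.join(extra)}")
    values = {k: float(raw[k]) for k in PARAM_KEYS}
    return ParameterSet(name=str(name), **values)


def as_params(spec: Union[str, Path, ParameterSet]) -> ParameterSet:
    """Resolve a preset name, file path or ParameterSet to a ParameterSet."""
    if isinstance(spec, ParameterSet):
        return spec
    if isinstance(spec, str) and spec in _PRESETS:
        return preset(spec)
    return read_params(spec)
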