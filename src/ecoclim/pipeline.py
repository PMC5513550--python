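"""End-to-end runs per site and per grid: natural, irrigated and composite scenarios.

``run_location`` chains the stages deterministically:

    monthly normals -> weekly climate -> irrigation top-up -> evaporative
    demand -> soil-moisture bucket (spin-up) -> TI/MI/GI -> stresses ->
    Ecoclimatic Index

``run_grid`` evaluates every cell under both the natural-rainfall and the
irrigated scenario and composes them through a boolean irrigation mask:
irrigated cells take the irrigated-scenario EI, the rest the natural one
(the composite risk map).  ``phenology`` exports the 52-week index
trajectories under both scenarios for seasonal-abundance comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import growth, hydrology, stress
from .climate_io import N_WEEKS, LocationClimate, monthly_to_weekly
from .ecoclimatic import AnnualIndices, classify_ei, ecoclimatic_index
from .hydrology import IrrigationScenario
from .params import ParameterSet

__all__ = [
    "RiskGrid",
    "PhenologyTable",
    "run_location",
    "run_weekly",
    "run_grid",
    "phenology",
    "write_risk_grid",
    "read_risk_grid",
    "write_phenology",
    "read_phenology",
]


@dataclass
class RiskGrid:
    """Gridded EI under natural, irrigated and composite scenarios."""

    nrow: int
    ncol: int
    lat: np.ndarray
    lon: np.ndarray
    ei_natural: np.ndarray
    ei_irrigated: np.ndarray
    ei_composite: np.ndarray
    irrigated_mask: np.ndarray

    def __post_init__(self) -> None:
        n = self.nrow * self.ncol
        if n <= 0:
            raise ValueError("grid must contain at least one cell")
        for name in ("lat", "lon", "ei_natural", "ei_irrigated", "ei_composite"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have nrow*ncol = {n} entries")
            setattr(self, name, arr)
        self.irrigated_mask = np.asarray(self.irrigated_mask, dtype=bool)
        if self.irrigated_mask.shape != (n,):
            raise ValueError(f"irrigated_mask must have {n} entries")
        expected = np.where(self.irrigated_mask, self.ei_irrigated, self.ei_natural)
        if not np.allclose(self.ei_composite, expected):
            raise ValueError("ei_composite violates the per-cell mask selection rule")

    def to_dataframe(self) -> pd.DataFrame:
        n = self.nrow * self.ncol
        rows, cols = np.divmod(np.arange(n), self.ncol)
        return pd.DataFrame({
            "row": rows, "col": cols,
            "lat": self.lat, "lon": self.lon,
            "ei_natural": self.ei_natural,
            "ei_irrigated": self.ei_irrigated,
            "ei_composite": self.ei_composite,
            "irrigated_mask": self.irrigated_mask.astype(int),
        })

    def to_xarray(self):
        """Georeferenced (lat/lon-indexed) dataset with one variable per EI layer.

        Requires a regular grid (constant lat per row, lon per column).
        """
        import xarray as xr

        lat2 = self.lat.reshape(self.nrow, self.ncol)
        lon2 = self.lon.reshape(self.nrow, self.ncol)
        coords = {"lat": lat2[:, 0], "lon": lon2[0, :]}
        data = {
            name: (("lat", "lon"), getattr(self, name).reshape(self.nrow, self.ncol))
            for name in ("ei_natural", "ei_irrigated", "ei_composite")
        }
        data["irrigated_mask"] = (("lat", "lon"),
                                  self.irrigated_mask.reshape(self.nrow, self.ncol))
        return xr.Dataset(data, coords=coords)


@dataclass
class PhenologyTable:
    """Weekly index trajectories under natural and irrigated scenarios."""

    week: np.ndarray           # 1..52
    ti: np.ndarray
    mi_natural: np.ndarray
    mi_irrigated: np.ndarray
    gi_natural: np.ndarray
    gi_irrigated: np.ndarray

    def __post_init__(self) -> None:
        for name in ("week", "ti", "mi_natural", "mi_irrigated",
                     "gi_natural", "gi_irrigated"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_WEEKS,):
                raise ValueError(f"{name} must have {N_WEEKS} entries")
            setattr(self, name, arr)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "week": self.week.astype(int),
            "ti": self.ti,
            "mi_natural": self.mi_natural,
            "mi_irrigated": self.mi_irrigated,
            "gi_natural": self.gi_natural,
            "gi_irrigated": self.gi_irrigated,
        })


def run_weekly(c: LocationClimate, p: ParameterSet,
               scen: Optional[IrrigationScenario] = None,
               k_et: float = hydrology.K_ET) -> growth.WeeklySeries:
    """Weekly series (TI, MI, GI, degree-days) for one site under one scenario."""
    wk = monthly_to_weekly(c)
    precip_eff = hydrology.apply_irrigation(wk.precip, c.lat, scen)
    ep = hydrology.potential_evapotranspiration(wk.tavg, wk.rh, k_et=k_et)
    bucket = hydrology.run_bucket(precip_eff, ep)
    ti = growth.temperature_index(wk.tavg, p)
    mi = growth.moisture_index(bucket.sm, p)
    gi = growth.weekly_growth_index(ti, mi)
    dd = growth.weekly_degree_days(wk.tavg, p.DV0)
    dd_cs = growth.weekly_degree_days(wk.tavg, p.DVCS)
    series = growth.WeeklySeries(ti=ti, mi=mi, gi=gi, dd=dd, dd_cs=dd_cs)
    # stash intermediates for annual assembly without re-running the bucket
    series.tavg = wk.tavg          # type: ignore[attr-defined]
    series.sm = bucket.sm          # type: ignore[attr-defined]
    return series


def run_location(c: LocationClimate, p: ParameterSet,
                 scen: Optional[IrrigationScenario] = None,
                 k_et: float = hydrology.K_ET) -> AnnualIndices:
    """Full pipeline for one site: deterministic composition of every stage."""
    series = run_weekly(c, p, scen, k_et=k_et)
    gi_a = growth.annual_growth_index(series.gi)
    dd_annual = float(np.sum(series.dd))
    stresses = stress.compute_stresses(series.tavg, series.sm, series.dd_cs, p)
    ei = ecoclimatic_index(gi_a, stresses, dd_annual, p)
    return AnnualIndices(gi_a=gi_a, stresses=stresses, dd_annual=dd_annual,
                         ei=ei, ei_class=classify_ei(ei))


def run_grid(cells: Sequence[LocationClimate], nrow: int, ncol: int,
             p: ParameterSet, irrigated_mask: Sequence[bool],
             scen: IrrigationScenario = IrrigationScenario()) -> RiskGrid:
    """Evaluate a flattened row-major grid under both scenarios and compose them."""
    cells = list(cells)
    if len(cells) == 0:
        raise ValueError("grid must contain at least one cell")
    if len(cells) != nrow * ncol:
        raise ValueError(f"expected {nrow * ncol} cells, got {len(cells)}")
    mask = np.asarray(irrigated_mask, dtype=bool)
    if mask.shape != (len(cells),):
        raise ValueError("irrigated_mask length must match the number of cells")
    ei_nat = np.array([run_location(c, p, None).ei for c in cells])
    ei_irr = np.array([run_location(c, p, scen).ei for c in cells])
    ei_comp = np.where(mask, ei_irr, ei_nat)
    return RiskGrid(
        nrow=nrow, ncol=ncol,
        lat=np.array([c.lat for c in cells]),
        lon=np.array([c.lon for c in cells]),
        ei_natural=ei_nat, ei_irrigated=ei_irr, ei_composite=ei_comp,
        irrigated_mask=mask,
    )


def phenology(c: LocationClimate, p: ParameterSet,
              scen: IrrigationScenario = IrrigationScenario()) -> PhenologyTable:
    """52-week TI/MI/GI trajectories under natural rainfall and under irrigation."""
    nat = run_weekly(c, p, None)
    irr = run_weekly(c, p, scen)
    return PhenologyTable(
        week=np.arange(1, N_WEEKS + 1),
        ti=nat.ti,
        mi_natural=nat.mi, mi_irrigated=irr.mi,
        gi_natural=nat.gi, gi_irrigated=irr.gi,
    )


def write_risk_grid(grid: RiskGrid, path: Union[str, Path]) -> None:
    """Delimited (CSV) export, one row per cell; bit-exact round-trip."""
    df = grid.to_dataframe()
    df.insert(0, "nrow", grid.nrow)
    df.insert(1, "ncol", grid.ncol)
    df.to_csv(path, index=False)


def read_risk_grid(path: Union[str, Path]) -> RiskGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"risk grid file {path} is empty")
    nrow, ncol = int(df["nrow"].iloc[0]), int(df["ncol"].iloc[0])
    df = df.sort_values(["row", "col"]).reset_index(drop=True)
    return RiskGrid(
        nrow=nrow, ncol=ncol,
        lat=df["lat"].to_numpy(), lon=df["lon"].to_numpy(),
        ei_natural=df["ei_natural"].to_numpy(),
        ei_irrigated=df["ei_irrigated"].to_numpy(),
        ei_composite=df["ei_composite"].to_numpy(),
        irrigated_mask=df["irrigated_mask"].to_numpy().astype(bool),
    )


def write_phenology(table: PhenologyTable, path: Union[str, Path]) -> None:
    """Delimited (CSV) export, one row per week; bit-exact round-trip."""
    table.to_dataframe().to_csv(path, index=False)


def read_phenology(path: Union[str, Path]) -> PhenologyTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"phenology file {path} is empty")
    return PhenologyTable(
        week=df["week"].to_numpy(),
        ti=df["ti"].to_numpy(),
        mi_natural=df["mi_natural"].to_numpy(),
        mi_irrigated=df["mi_irrigated"].to_numpy(),
        gi_natural=df["gi_natural"].to_numpy(),
        gi_irrigated=df["gi_irrigated"].to_numpy(),
    )
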