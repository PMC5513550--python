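"""Monthly climate normals: containers, tabular I/O and weekly expansion.

The model is driven by long-term monthly climate normals per location:
minimum and maximum temperature (°C), precipitation (mm/month) and
relative humidity at 09h00 and 15h00 (fractions), i.e. the variable set of
gridded normals products such as CliMond.  The engine itself runs on a
52-week year, so :func:`monthly_to_weekly` expands the 12 monthly values
into 52 weekly ones.

Calendar convention: a 364-day year of 52 seven-day weeks and 12 equal
months of 364/12 days; week 1 starts 1 January.  Temperatures and humidity
are interpolated piecewise-linearly between month midpoints with periodic
Dec->Jan wrap; precipitation is spread as a piecewise-constant daily rate
per month and integrated over each week, which conserves the annual total
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LocationClimate",
    "WeeklyClimate",
    "read_climate_table",
    "write_climate_table",
    "monthly_to_weekly",
    "N_WEEKS",
    "DAYS_PER_WEEK",
]

N_WEEKS = 52
DAYS_PER_WEEK = 7.0
DAYS_PER_YEAR = N_WEEKS * DAYS_PER_WEEK  # 364
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
VARIABLES = ("tmin", "tmax", "precip", "rh09", "rh15")


def _as12(name: str, values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (12,):
        raise ValueError(f"{name} must have exactly 12 monthly values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class LocationClimate:
    """Monthly climate normals for one site or grid cell.

    ``lat`` is in degrees, south negative — the sign selects the local
    summer half-year for the irrigation scenario.
    """

    site_id: str
    lat: float
    lon: float
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    row: int = -1  # optional grid indices; -1 for plain site lists
    col: int = -1

    def __post_init__(self) -> None:
        self.tmin = _as12("tmin", self.tmin)
        self.tmax = _as12("tmax", self.tmax)
        self.precip = _as12("precip", self.precip)
        self.rh09 = _as12("rh09", self.rh09)
        self.rh15 = _as12("rh15", self.rh15)
        if not -90 <= self.lat <= 90:
            raise ValueError(f"site {self.site_id}: latitude {self.lat} outside [-90, 90]")
        bad = np.nonzero(self.tmin > self.tmax)[0]
        if bad.size:
            m = int(bad[0])
            raise ValueError(
                f"site {self.site_id}: tmin > tmax in {MONTH_NAMES[m]} "
                f"({self.tmin[m]} > {self.tmax[m]})"
            )
        bad = np.nonzero(self.precip < 0)[0]
        if bad.size:
            m = int(bad[0])
            raise ValueError(
                f"site {self.site_id}: negative precipitation in {MONTH_NAMES[m]}"
            )
        for name in ("rh09", "rh15"):
            rh = getattr(self, name)
            bad = np.nonzero((rh < 0) | (rh > 1))[0]
            if bad.size:
                m = int(bad[0])
                raise ValueError(
                    f"site {self.site_id}: {name} outside [0, 1] in {MONTH_NAMES[m]}"
                )

    @property
    def tavg(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)


@dataclass
class WeeklyClimate:
    """One 52-week year of climate inputs for the engine."""

    tavg: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray  # mm/week
    rh: np.ndarray      # fraction, mean of 09h00 and 15h00

    def __post_init__(self) -> None:
        for name in ("tavg", "tmin", "tmax", "precip", "rh"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_WEEKS,):
                raise ValueError(f"{name} must have {N_WEEKS} weekly values")
            setattr(self, name, arr)


def _interp_periodic(monthly: np.ndarray) -> np.ndarray:
    """Linear interpolation from month midpoints to week midpoints, wrapping Dec->Jan."""
    month_mid = (np.arange(12) + 0.5) * DAYS_PER_MONTH
    week_mid = (np.arange(N_WEEKS) + 0.5) * DAYS_PER_WEEK
    # pad one month on each side for the periodic wrap
    xp = np.concatenate(([month_mid[-1] - DAYS_PER_YEAR], month_mid, [month_mid[0] + DAYS_PER_YEAR]))
    fp = np.concatenate(([monthly[-1]], monthly, [monthly[0]]))
    return np.interp(week_mid, xp, fp)


def _weekly_precip(monthly: np.ndarray) -> np.ndarray:
    """Integrate a piecewise-constant monthly precipitation rate over each week.

    Exactly conserves the annual total.
    """
    rate = monthly / DAYS_PER_MONTH  # mm/day within each month
    out = np.zeros(N_WEEKS)
    for w in range(N_WEEKS):
        lo, hi = w * DAYS_PER_WEEK, (w + 1) * DAYS_PER_WEEK
        for m in range(12):
            mlo, mhi = m * DAYS_PER_MONTH, (m + 1) * DAYS_PER_MONTH
            overlap = min(hi, mhi) - max(lo, mlo)
            if overlap > 0:
                out[w] += overlap * rate[m]
    return out


def monthly_to_weekly(c: LocationClimate) -> WeeklyClimate:
    """Expand monthly normals to the engine's 52-week year."""
    tmin = _interp_periodic(c.tmin)
    tmax = _interp_periodic(c.tmax)
    rh = 0.5 * (_interp_periodic(c.rh09) + _interp_periodic(c.rh15))
    precip = _weekly_precip(c.precip)
    return WeeklyClimate(tavg=0.5 * (tmin + tmax), tmin=tmin, tmax=tmax,
                         precip=precip, rh=rh)


def _columns() -> List[str]:
    cols = ["site_id", "lat", "lon", "row", "col"]
    for var in VARIABLES:
        cols += [f"{var}_{m:02d}" for m in range(1, 13)]
    return cols


def write_climate_table(sites: Iterable[LocationClimate], path: Union[str, Path]) -> None:
    """Write sites as a delimited (CSV) climate table."""
    rows = []
    for c in sites:
        row = {"site_id": c.site_id, "lat": c.lat, "lon": c.lon,
               "row": c.row, "col": c.col}
        for var in VARIABLES:
            vals = getattr(c, var)
            for m in range(12):
                row[f"{var}_{m + 1:02d}"] = vals[m]
        rows.append(row)
    pd.DataFrame(rows, columns=_columns()).to_csv(path, index=False)


def read_climate_table(path: Union[str, Path]) -> List[LocationClimate]:
    """Read a climate table (CSV): site_id, lat, lon, then 12-month blocks per variable.

    Validation failures are reported per row with the offending site_id.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"site_id", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table {path} missing columns: {sorted(missing)}")
    for var in VARIABLES:
        cols = [f"{var}_{m:02d}" for m in range(1, 13)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"climate table {path} missing columns: {missing}")
    sites = []
    for _, rec in df.iterrows():
        kwargs = {
            var: np.array([rec[f"{var}_{m:02d}"] for m in range(1, 13)], dtype=float)
            for var in VARIABLES
        }
        sites.append(
            LocationClimate(
                site_id=str(rec["site_id"]), lat=float(rec["lat"]), lon=float(rec["lon"]),
                row=int(rec.get("row", -1)), col=int(rec.get("col", -1)),
                **kwargs,
            )
        )
    return sites
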