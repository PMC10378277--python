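"""Long-format multivariate space-time observation tables and seasonality.

Observations live in a tidy table with one row per (station, month, variable)
and fixed station coordinates in projected km.  The only preprocessing the
analysis needs is removal of the per-station, per-variable monthly seasonal
cycle: monthly means over the record are computed for each station and
subtracted, and can later be added back to predictions (including at grid
nodes, where station profiles are interpolated by inverse-distance weighting).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ObservationTable",
    "SeasonalProfile",
    "LoadError",
    "read_observations",
    "deseasonalize",
    "reseasonalize",
    "calendar_month",
]

#: canonical CSV column names (file dialect -> internal names)
CSV_COLUMNS = {"station": "station", "x_km": "x", "y_km": "y",
               "t": "t", "variable": "variable", "value": "value"}
_INTERNAL = ["station", "x", "y", "t", "variable", "value"]


class LoadError(ValueError):
    """Raised when an observation file violates the table contract."""


def calendar_month(t, phase: int = 0) -> np.ndarray:
    """Map a 1-based consecutive month index to a calendar month 1..12."""
    t = np.asarray(t, dtype=int)
    return ((t - 1 - phase) % 12) + 1


class ObservationTable:
    """Validated long-format observation table.

    Parameters
    ----------
    data:
        DataFrame with columns station, x, y, t, variable, value.  ``t`` is a
        1-based consecutive integer month index.
    role:
        ``"raw"`` for observations on the original scale, ``"residual"``
        after seasonal removal.
    """

    def __init__(self, data: pd.DataFrame, role: str = "raw") -> None:
        missing = [c for c in _INTERNAL if c not in data.columns]
        if missing:
            raise LoadError(f"missing columns: {missing}")
        if role not in ("raw", "residual"):
            raise ValueError(f"role must be 'raw' or 'residual', got {role!r}")
        df = data.loc[:, _INTERNAL].copy()
        df["station"] = df["station"].astype(str)
        df["variable"] = df["variable"].astype(str)
        for col in ("x", "y", "value"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        df["t"] = df["t"].astype(int)
        dup = df.duplicated(subset=["station", "t", "variable"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["station", "t", "variable"]].tolist()
            raise LoadError(
                f"duplicate (station, t, variable) keys, first duplicate: {tuple(key)}"
            )
        ncoords = df.groupby("station")[["x", "y"]].nunique()
        moved = ncoords[(ncoords > 1).any(axis=1)]
        if len(moved):
            raise LoadError(
                f"stations with non-constant coordinates: {list(moved.index)}"
            )
        self.data = df.reset_index(drop=True)
        self.role = role

    # -- introspection ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["variable"].unique()))

    @property
    def stations(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["station"].unique()))

    @property
    def time_range(self) -> tuple[int, int]:
        return int(self.data["t"].min()), int(self.data["t"].max())

    @property
    def n_months(self) -> int:
        t0, t1 = self.time_range
        return t1 - t0 + 1

    def station_coords(self) -> pd.DataFrame:
        """Station -> (x, y) lookup, one row per station."""
        return (
            self.data.groupby("station")[["x", "y"]].first().loc[list(self.stations)]
        )

    def counts(self) -> pd.DataFrame:
        """Per-variable station and time-point counts."""
        g = self.data.groupby("variable")
        return pd.DataFrame(
            {"n_stations": g["station"].nunique(), "n_times": g["t"].nunique(),
             "n_obs": g.size()}
        )

    def wide(self, variable: str) -> pd.DataFrame:
        """Stations x months value matrix for one variable (NaN = missing)."""
        if variable not in self.variables:
            raise KeyError(f"unknown variable {variable!r}")
        sub = self.data[self.data["variable"] == variable]
        t0, t1 = self.time_range
        return sub.pivot(index="station", columns="t", values="value").reindex(
            index=list(self.stations), columns=range(t0, t1 + 1)
        )

    def filter(self, *, variables: Iterable[str] | None = None,
               months: Iterable[int] | None = None) -> "ObservationTable":
        df = self.data
        if variables is not None:
            df = df[df["variable"].isin(set(variables))]
        if months is not None:
            df = df[df["t"].isin(set(int(m) for m in months))]
        return ObservationTable(df.copy(), role=self.role)

    # -- IO -----------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.data.rename(columns={v: k for k, v in CSV_COLUMNS.items()})
        out.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ObservationTable(role={self.role!r}, n={len(self)}, "
            f"p={len(self.variables)}, stations={len(self.stations)}, "
            f"months={self.n_months})"
        )


def read_observations(path, schema: dict | None = None) -> ObservationTable:
    """Read an observation CSV (columns station,x_km,y_km,t,variable,value).

    ``schema`` may rename file columns, mapping file names to the canonical
    dialect names.  Errors identify offending rows where possible.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path.name}: missing columns {missing}")
    df = df.rename(columns=CSV_COLUMNS)
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise LoadError(f"{path.name}: non-numeric values at file rows {rows}")
    df = df[df["value"].notna()]
    # months parsed to consecutive integer index anchored at the minimum
    t = df["t"].astype(int)
    df = df.assign(t=t - t.min() + 1)
    try:
        return ObservationTable(df, role="raw")
    except LoadError as err:
        raise LoadError(f"{path.name}: {err}") from err


@dataclasses.dataclass
class SeasonalProfile:
    """Per (station, variable) monthly means plus station coordinates.

    ``table`` has columns station, variable, month (1..12), mean.
    """

    table: pd.DataFrame
    coords: pd.DataFrame
    phase: int = 0

    def __post_init__(self) -> None:
        counts = self.table.groupby(["station", "variable"])["month"].nunique()
        short = counts[counts != 12]
        if len(short):
            raise ValueError(
                f"profiles must have 12 monthly entries; incomplete: "
                f"{list(short.index)[:5]}"
            )
        self._lookup = self.table.set_index(["station", "variable", "month"])[
            "mean"
        ].sort_index()

    def value(self, station: str, variable: str, month: int) -> float:
        try:
            return float(self._lookup.loc[(station, variable, int(month))])
        except KeyError:
            raise KeyError(f"no seasonal profile for {(station, variable)}")

    def values_for(self, stations, variables, t) -> np.ndarray:
        months = calendar_month(t, self.phase)
        return np.array(
            [self.value(s, v, m) for s, v, m in zip(stations, variables, months)]
        )

    def interpolate(self, x: float, y: float, variable: str, month: int,
                    power: float = 2.0) -> float:
        """Seasonal value at an arbitrary point by inverse-distance weighting.

        Exact at station locations; uses all stations with a profile for the
        requested variable.
        """
        sub = self.table[
            (self.table["variable"] == variable) & (self.table["month"] == int(month))
        ]
        if sub.empty:
            raise KeyError(f"no seasonal profile for variable {variable!r}")
        xy = self.coords.loc[sub["station"]].to_numpy(dtype=float)
        d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
        vals = sub["mean"].to_numpy(dtype=float)
        near = d < 1e-9
        if near.any():
            return float(vals[near][0])
        w = 1.0 / d**power
        return float(np.sum(w * vals) / np.sum(w))

    def to_csv(self, path) -> None:
        merged = self.table.merge(
            self.coords.rename(columns={"x": "x_km", "y": "y_km"}),
            left_on="station", right_index=True,
        )
        merged.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, phase: int = 0) -> "SeasonalProfile":
        df = pd.read_csv(path)
        coords = (
            df.groupby("station")[["x_km", "y_km"]]
            .first()
            .rename(columns={"x_km": "x", "y_km": "y"})
        )
        return cls(df[["station", "variable", "month", "mean"]].copy(), coords,
                   phase=phase)


def deseasonalize(
    table: ObservationTable, phase: int = 0
) -> tuple[ObservationTable, SeasonalProfile]:
    """Remove the per-station monthly mean cycle from a raw table.

    Every (station, variable) must have at least one observation in each of
    the 12 calendar months; empty cells are reported explicitly.  Returns the
    residual table and the seasonal profile needed to restore the original
    scale.
    """
    if table.role != "raw":
        raise ValueError("deseasonalize expects a raw table")
    df = table.data.copy()
    df["month"] = calendar_month(df["t"].to_numpy(), phase)
    means = (
        df.groupby(["station", "variable", "month"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )
    counts = means.groupby(["station", "variable"])["month"].nunique()
    short = counts[counts != 12]
    if len(short):
        missing_cells = []
        for station, variable in short.index[:5]:
            have = set(
                means[(means["station"] == station) & (means["variable"] == variable)][
                    "month"
                ]
            )
            missing_cells.append((station, variable, sorted(set(range(1, 13)) - have)))
        raise ValueError(
            f"empty calendar-month cells (station, variable, months): {missing_cells}"
        )
    merged = df.merge(means, on=["station", "variable", "month"], how="left")
    merged["value"] = merged["value"] - merged["mean"]
    residual = ObservationTable(merged[_INTERNAL], role="residual")
    profile = SeasonalProfile(means, table.station_coords(), phase=phase)
    return residual, profile


def reseasonalize(
    table: ObservationTable, profile: SeasonalProfile
) -> ObservationTable:
    """Add the seasonal profile back to a residual table."""
    if table.role != "residual":
        raise ValueError("reseasonalize expects a residual table")
    df = table.data.copy()
    seasonal = profile.values_for(
        df["station"].to_numpy(), df["variable"].to_numpy(), df["t"].to_numpy()
    )
    df["value"] = df["value"] + seasonal
    return ObservationTable(df, role="raw")
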