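"""Rectilinear grid and gridded ocean-state containers with CF-NetCDF I/O.

Conventions
-----------
* Depth is positive downward; layers are ordered surface -> bottom and every
  vertical integral weights by layer thickness.
* Concentrations are stored in mmol m-3.  Readers convert umol kg-1 inputs
  using a fixed reference density of 1025 kg m-3 (recorded in metadata).
* Missing values (land, below bottom) are NaN; arithmetic propagates them.
* Coordinates are cell centers; distance to coast uses the haversine formula
  on a sphere of radius 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_M = 6_371_000.0
REFERENCE_DENSITY = 1025.0  # kg m-3, for umol/kg -> mmol/m3 conversion

#: state variables carried by :class:`OceanState`, with internal units
STATE_VARS = {
    "T": "degC",
    "S": "psu",
    "O2": "mmol m-3",
    "DIC": "mmol m-3",
    "TA": "meq m-3",
    "NH4": "mmol m-3",
    "NO3": "mmol m-3",
    "PO4": "mmol m-3",
    "SiO3": "mmol m-3",
    "NPP": "mmol C m-3 d-1",
    "RESP": "mmol C m-3 d-1",
    "u": "m s-1",
    "v": "m s-1",
}

#: internal name -> CF-NetCDF variable name
_NC_NAMES = {
    "T": "temp",
    "S": "salt",
    "O2": "O2",
    "DIC": "DIC",
    "TA": "Alk",
    "NH4": "NH4",
    "NO3": "NO3",
    "PO4": "PO4",
    "SiO3": "SiO3",
    "NPP": "NPP",
    "RESP": "RESP",
    "u": "u",
    "v": "v",
}
_INTERNAL_NAMES = {v: k for k, v in _NC_NAMES.items()}


class GridError(ValueError):
    """Malformed or degenerate grid."""


class FormatError(ValueError):
    """File does not follow the expected CF-NetCDF dialect."""


@dataclass
class Grid:
    """Rectilinear cell-centered grid with bathymetry and derived geometry.

    Parameters
    ----------
    lon, lat : 1-D arrays of cell-center coordinates (degrees east / north).
    z_centers : layer-center depths, m positive downward, strictly increasing.
    z_thickness : layer thicknesses, m, positive.
    bathymetry : (ny, nx) seafloor depth, m positive; 0 on land.
    land_mask : (ny, nx) boolean, True on land.
    """

    lon: np.ndarray
    lat: np.ndarray
    z_centers: np.ndarray
    z_thickness: np.ndarray
    bathymetry: np.ndarray
    land_mask: np.ndarray
    cell_area: Optional[np.ndarray] = None
    dist_coast: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.z_thickness = np.asarray(self.z_thickness, dtype=float)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if np.any(np.diff(self.z_centers) <= 0):
            raise GridError("z_centers must be strictly increasing")
        if np.any(self.z_thickness <= 0):
            raise GridError("z_thickness must be positive")
        if np.any(self.bathymetry < 0):
            raise GridError("bathymetry must be non-negative")
        if self.bathymetry.shape != (self.lat.size, self.lon.size):
            raise GridError("bathymetry shape does not match lon/lat")
        if self.land_mask.shape != self.bathymetry.shape:
            raise GridError("land_mask shape does not match bathymetry")
        if self.cell_area is None:
            self.cell_area = cell_areas(self)
        if self.dist_coast is None and self.land_mask.any() and (~self.land_mask).any():
            self.dist_coast = compute_dist_coast(self)

    @property
    def shape(self) -> tuple:
        return self.bathymetry.shape

    @property
    def nz(self) -> int:
        return self.z_centers.size

    def z_edges(self) -> np.ndarray:
        """Layer interface depths (nz+1,), from cumulative thickness."""
        return np.concatenate([[0.0], np.cumsum(self.z_thickness)])

    def wet_mask3d(self) -> np.ndarray:
        """(nz, ny, nx) True where the layer center is above the seafloor on ocean cells."""
        ocean = ~self.land_mask
        return (self.z_centers[:, None, None] < self.bathymetry[None]) & ocean[None]

    def alongshore_index(self) -> np.ndarray:
        """Integer order of coastal (land-adjacent ocean) cells, south to north.

        Returns an (n_coastal, 2) array of (j, i) indices sorted by latitude,
        ties broken by longitude — the ordering used for alongshore averaging.
        """
        coastal = _land_adjacent_ocean(self.land_mask)
        jj, ii = np.nonzero(coastal)
        order = np.lexsort((self.lon[ii], self.lat[jj]))
        return np.stack([jj[order], ii[order]], axis=1)


@dataclass
class OceanState:
    """4-D ocean state on a :class:`Grid`: fields on (time, depth, y, x)."""

    time: pd.DatetimeIndex
    fields: Dict[str, np.ndarray]
    scenario_label: str = ""
    attrs: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        shapes = {v.shape for v in self.fields.values()}
        if len(shapes) > 1:
            raise GridError(f"inconsistent field shapes: {shapes}")
        for name, arr in self.fields.items():
            if arr.shape[0] != len(self.time):
                raise GridError(f"field {name!r} first dim != time length")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.fields[name]

    def copy(self) -> "OceanState":
        return OceanState(
            time=self.time.copy(),
            fields={k: v.copy() for k, v in self.fields.items()},
            scenario_label=self.scenario_label,
            attrs=dict(self.attrs),
        )


def nanmean_quiet(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """nanmean without the all-NaN RuntimeWarning (all-NaN slices give NaN)."""
    a = np.asarray(a, dtype=float)
    cnt = np.isfinite(a).sum(axis=axis)
    total = np.nansum(a, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * (EARTH_RADIUS_M / 1000.0) * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _land_adjacent_ocean(land_mask: np.ndarray) -> np.ndarray:
    """Boolean mask of ocean cells 4-adjacent to land."""
    land = land_mask
    pad = np.pad(land, 1, mode="edge")
    neighbour_land = pad[:-2, 1:-1] | pad[2:, 1:-1] | pad[1:-1, :-2] | pad[1:-1, 2:]
    return (~land) & neighbour_land


def _ocean_adjacent_land(land_mask: np.ndarray) -> np.ndarray:
    """Boolean mask of land cells 4-adjacent to ocean (the coastline cells)."""
    ocean = ~land_mask
    pad = np.pad(ocean, 1, mode="edge")
    neighbour_ocean = pad[:-2, 1:-1] | pad[2:, 1:-1] | pad[1:-1, :-2] | pad[1:-1, 2:]
    return land_mask & neighbour_ocean


def compute_dist_coast(grid: Grid) -> np.ndarray:
    """Great-circle distance (km) from each ocean cell center to the nearest
    coastline (ocean-adjacent land) cell center.  Land cells get 0.

    Deterministic; interior land cells do not affect the result.
    """
    land = grid.land_mask
    if not land.any() or land.all():
        raise GridError("grid must contain both land and ocean cells")
    coast = _ocean_adjacent_land(land)
    cj, ci = np.nonzero(coast)
    clon = grid.lon[ci]
    clat = grid.lat[cj]
    lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
    oj, oi = np.nonzero(~land)
    dist = np.zeros(grid.shape, dtype=float)
    # chunk over ocean cells to bound memory on large grids
    step = 20000
    for k in range(0, oj.size, step):
        sj = oj[k : k + step]
        si = oi[k : k + step]
        d = haversine_km(
            lon2d[sj, si][:, None], lat2d[sj, si][:, None], clon[None, :], clat[None, :]
        )
        dist[sj, si] = d.min(axis=1)
    return dist


def cell_areas(grid: Grid) -> np.ndarray:
    """Spherical quadrilateral area per cell, m^2: R^2 * dlam * (sin(phi2) - sin(phi1)).

    Cell edges are midpoints between neighbouring centers, extrapolated at the
    domain boundary.
    """
    lon, lat = grid.lon, grid.lat
    if lon.size > 1 and not (np.all(np.diff(lon) > 0) or np.all(np.diff(lon) < 0)):
        raise GridError("lon must be monotone")
    if lat.size > 1 and not (np.all(np.diff(lat) > 0) or np.all(np.diff(lat) < 0)):
        raise GridError("lat must be monotone")

    def edges(c: np.ndarray) -> np.ndarray:
        if c.size == 1:
            # degenerate single-cell axis: assume 1-degree span
            return np.array([c[0] - 0.5, c[0] + 0.5])
        mid = 0.5 * (c[:-1] + c[1:])
        first = c[0] - (mid[0] - c[0])
        last = c[-1] + (c[-1] - mid[-1])
        return np.concatenate([[first], mid, [last]])

    lon_e = np.radians(edges(lon))
    lat_e = np.radians(edges(lat))
    dlam = np.abs(np.diff(lon_e))
    dsin = np.abs(np.diff(np.sin(lat_e)))
    return EARTH_RADIUS_M**2 * dsin[:, None] * dlam[None, :]


def write_state(state: OceanState, grid: Grid, path) -> None:
    """Write state + grid to CF-NetCDF (classic format, scipy backend)."""
    coords = {
        "time": ("time", state.time),
        "depth": ("depth", grid.z_centers, {"units": "m", "positive": "down"}),
        "eta": ("eta", grid.lat, {"units": "degrees_north"}),
        "xi": ("xi", grid.lon, {"units": "degrees_east"}),
    }
    data_vars = {}
    for name, arr in state.fields.items():
        data_vars[_NC_NAMES[name]] = (
            ("time", "depth", "eta", "xi"),
            np.asarray(arr),
            {"units": STATE_VARS[name]},
        )
    data_vars["z_thickness"] = (("depth",), grid.z_thickness, {"units": "m"})
    data_vars["bathymetry"] = (("eta", "xi"), grid.bathymetry, {"units": "m"})
    data_vars["land_mask"] = (("eta", "xi"), grid.land_mask.astype(np.int8), {})
    ds = xr.Dataset(data_vars, coords=coords)
    ds.attrs["scenario_label"] = state.scenario_label
    ds.attrs["Conventions"] = "CF-1.8"
    ds.attrs["reference_density_kg_m3"] = REFERENCE_DENSITY
    for k, v in state.attrs.items():
        ds.attrs.setdefault(k, v)
    ds.to_netcdf(path, engine="scipy")


def read_state(path) -> tuple:
    """Read a CF-NetCDF state file written by :func:`write_state` (or compatible).

    Returns ``(state, grid)``.  Variables in umol kg-1 are converted to
    mmol m-3 with the fixed reference density.  Raises :class:`FormatError`
    if a required variable is missing, :class:`GridError` on shape mismatch.
    """
    ds = xr.open_dataset(path, engine="scipy", decode_times=True)
    try:
        missing = [nc for nc in _NC_NAMES.values() if nc not in ds]
        if missing:
            raise FormatError(f"missing required variable(s): {', '.join(missing)}")
        for aux in ("z_thickness", "bathymetry", "land_mask"):
            if aux not in ds:
                raise FormatError(f"missing required variable(s): {aux}")
        time = pd.DatetimeIndex(np.asarray(ds["time"].values))
        shape4 = (time.size, ds.sizes["depth"], ds.sizes["eta"], ds.sizes["xi"])
        fields = {}
        for internal, nc in _NC_NAMES.items():
            var = ds[nc]
            if var.shape != shape4:
                raise GridError(f"variable {nc!r} has shape {var.shape}, expected {shape4}")
            arr = np.asarray(var.values, dtype=float)
            units = str(var.attrs.get("units", "")).lower().replace(" ", "")
            if "kg-1" in units or "/kg" in units:
                arr = arr * (REFERENCE_DENSITY / 1000.0)  # umol/kg -> mmol/m3
            fields[internal] = arr
        grid = Grid(
            lon=np.asarray(ds["xi"].values, dtype=float),
            lat=np.asarray(ds["eta"].values, dtype=float),
            z_centers=np.asarray(ds["depth"].values, dtype=float),
            z_thickness=np.asarray(ds["z_thickness"].values, dtype=float),
            bathymetry=np.asarray(ds["bathymetry"].values, dtype=float),
            land_mask=np.asarray(ds["land_mask"].values) > 0,
        )
        state = OceanState(
            time=time,
            fields=fields,
            scenario_label=str(ds.attrs.get("scenario_label", "")),
            attrs={k: v for k, v in ds.attrs.items() if isinstance(v, str)},
        )
        return state, grid
    finally:
        ds.close()
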