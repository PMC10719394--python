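"""Seeded synthetic coastal-ocean generator.

Emulates the statistical structure the scenario diagnostics assume, on a
shelf/slope domain with a straight coastline on the eastern edge:

* bathymetry deepening offshore and crossing the 200 m isobath;
* background T/S/O2/DIC/TA/nutrient profiles with a late-summer (Aug-Oct)
  subsurface O2 / saturation-state minimum;
* outfall plume anomalies whose magnitude is exactly linear in each
  outfall's DIN load: NH4 near the discharge depth, NPP in the euphotic band
  (0-50 m), respiration peaking in the 50-150 m band and displaced
  downstream by the mean alongshore current, and O2/DIC following
  respiration through fixed stoichiometry (C:N 106:16, O2:C 150:106);
* a mean poleward alongshore current with a weak offshore component plus a
  seeded solenoidal eddy field from a smoothed random streamfunction.

The background (including the eddy realization) depends only on the seed, so
two scenarios generated with the same config differ exactly by their forced
anomalies; with all loads zero (CTRL) the anomalies are identically zero.
All concentration fields are floored at zero; the default amplitudes keep the
floor inactive so anomaly linearity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from eutroscen.effluent import EffluentResult, OutfallRecord
from eutroscen.grid import Grid, OceanState

KM_PER_DEG_LAT = 111.195  # spherical earth, R = 6371 km


class PlacementError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the desk-scale study conditions."""

    nx: int = 120
    ny: int = 90
    dx_km: float = 3.0
    n_land_columns: int = 3
    months: int = 24
    start: str = "2015-11"
    seed: int = 1234

    # bathymetry: depth = max_depth * (1 - exp(-d_offshore / efold))
    max_depth: float = 620.0
    bathy_efold_km: float = 20.0
    lat0: float = 32.6
    lon0: float = -119.9

    # background profiles
    sst_mean: float = 14.0
    sst_seasonal_amp: float = 4.0
    thermocline_depth: float = 50.0
    delta_T: float = 9.0
    s_surface: float = 33.3
    o2_deep: float = 40.0
    o2_surface_excess: float = 220.0
    oxycline_depth: float = 90.0
    o2_seasonal_amp: float = 25.0
    seasonal_center_depth: float = 100.0
    seasonal_depth_spread: float = 60.0
    dic_surface: float = 1950.0
    dic_gradient: float = 480.0
    dic_efold: float = 220.0
    ta_surface: float = 2230.0
    ta_gradient: float = 150.0
    ta_efold: float = 400.0
    nitracline_depth: float = 100.0

    # plume kernel and response gains
    plume_efold_km: float = 5.0
    plume_sigma_z: float = 10.0
    alongshore_stretch: float = 2.5
    downstream_shift_km: float = 8.0
    resp_center_depth: float = 100.0
    resp_sigma_z: float = 35.0
    euphotic_depth: float = 50.0
    gain_nh4: float = 3.0e-4  # mmol m-3 per (kg DIN/d) at the kernel peak
    gain_npp: float = 1.0e-4  # mmol C m-3 d-1 per (kg DIN/d)
    resp_fraction: float = 0.5  # respired fraction of plume NPP
    accumulation_days: float = 30.0  # O2/DIC response timescale
    c_to_n: float = 106.0 / 16.0
    o2_to_c: float = 150.0 / 106.0

    # circulation
    v_alongshore: float = 0.15  # m/s, poleward
    u_offshore: float = -0.03  # m/s (negative x = offshore)
    eddy_amplitude: float = 0.05  # m/s rms target
    eddy_smooth_cells: float = 4.0

    productivity_multiplier: float = 1.0  # interannual modulation knob (uncalibrated)

    def __post_init__(self) -> None:
        if self.months < 1:
            raise ValueError("months must be >= 1")
        if min(self.nx, self.ny, self.dx_km, self.plume_efold_km, self.plume_sigma_z) <= 0:
            raise ValueError("grid and kernel scales must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls(**overrides)

    def to_dict(self) -> Dict:
        return asdict(self)


def build_grid(config: SynthConfig) -> Grid:
    """Rectilinear grid with a straight eastern coastline and offshore-deepening
    shelf/slope bathymetry crossing 200 m."""
    nx, ny = config.nx, config.ny
    dlat = config.dx_km / KM_PER_DEG_LAT
    lat = config.lat0 + np.arange(ny) * dlat
    dlon = config.dx_km / (KM_PER_DEG_LAT * np.cos(np.radians(config.lat0 + ny * dlat / 2)))
    lon = config.lon0 + np.arange(nx) * dlon
    # coast: last n_land_columns at the eastern (high-x) edge are land
    i_coast = nx - config.n_land_columns  # first land column index
    d_off = (i_coast - 0.5 - np.arange(nx)) * config.dx_km  # km offshore of coast edge
    alongshore_mod = 1.0 + 0.08 * np.sin(2.0 * np.pi * np.arange(ny) / ny * 3.0)
    bathy = config.max_depth * (1.0 - np.exp(-np.clip(d_off, 0.0, None) / config.bathy_efold_km))
    bathy = bathy[None, :] * alongshore_mod[:, None]
    land = np.zeros((ny, nx), dtype=bool)
    land[:, i_coast:] = True
    bathy[land] = 0.0
    z_thickness = np.concatenate([np.full(20, 10.0), np.full(10, 40.0)])
    z_centers = np.cumsum(z_thickness) - z_thickness / 2.0
    return Grid(
        lon=lon,
        lat=lat,
        z_centers=z_centers,
        z_thickness=z_thickness,
        bathymetry=bathy,
        land_mask=land,
    )


def default_outfalls(config: SynthConfig) -> List[OutfallRecord]:
    """Five synthetic POTW outfalls along the coast: four secondary-treatment
    plants and one small plant already meeting low-DIN targets."""
    grid = build_grid(config)
    i_coast = config.nx - config.n_land_columns
    specs = [
        # (id, y-fraction, offshore km, depth m, flow m3/d, NH4, NO3NO2)
        ("PLANT_A", 0.18, 8.0, 60.0, 4.0e5, 37.9, 3.4),
        ("PLANT_B", 0.38, 6.0, 60.0, 3.2e5, 39.0, 2.5),
        ("PLANT_C", 0.55, 7.5, 75.0, 3.0e5, 36.5, 4.5),
        ("PLANT_D", 0.72, 9.0, 90.0, 1.6e5, 38.5, 3.0),
        ("PLANT_E", 0.86, 3.0, 25.0, 4.0e4, 2.0, 3.0),  # already low-DIN
    ]
    records = []
    for pid, fy, off_km, depth, flow, nh4, no3 in specs:
        j = int(round(fy * (config.ny - 1)))
        i = int(round(i_coast - 1 - off_km / config.dx_km))
        records.append(
            OutfallRecord(
                plant_id=pid,
                lon=float(grid.lon[i]),
                lat=float(grid.lat[j]),
                discharge_depth=depth,
                flow=flow,
                conc={
                    "NH4": nh4,
                    "NO3NO2": no3,
                    "PO4": 2.0,
                    "SiO3": 15.0,
                    "alkalinity": 2.5,
                    "organicC": 20.0,
                    "organicN": 3.0,
                    "organicP": 0.5,
                    "salt": 1.2,
                    "Fe": 50.0,
                },
            )
        )
    return records


def _month_axis(config: SynthConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.start, periods=config.months, freq="MS") + pd.Timedelta(days=14)


def _seasonal_factor(month: np.ndarray, center: float = 9.0, spread: float = 1.5) -> np.ndarray:
    """Late-summer bump peaking in September, periodic in the calendar."""
    d = np.minimum(np.abs(month - center), 12.0 - np.abs(month - center))
    return np.exp(-((d / spread) ** 2))


def _background(config: SynthConfig, grid: Grid, time: pd.DatetimeIndex) -> Dict[str, np.ndarray]:
    nz, (ny, nx) = grid.nz, grid.shape
    nt = len(time)
    z = grid.z_centers.reshape(1, nz, 1, 1)
    month = np.asarray(time.month, dtype=float).reshape(nt, 1, 1, 1)
    seas_t = np.cos(2.0 * np.pi * (month - 8.5) / 12.0)  # warm late summer
    bump = _seasonal_factor(month)
    subsurface = np.exp(-(((z - config.seasonal_center_depth) / config.seasonal_depth_spread) ** 2))
    surface_taper = np.exp(-z / config.thermocline_depth)

    T = (
        config.sst_mean
        + config.sst_seasonal_amp * seas_t * surface_taper
        - config.delta_T * (1.0 - np.exp(-z / config.thermocline_depth))
    )
    S = config.s_surface + 0.4 * (1.0 - np.exp(-z / 200.0))
    O2 = (
        config.o2_deep
        + config.o2_surface_excess * np.exp(-z / config.oxycline_depth)
        - config.o2_seasonal_amp * bump * subsurface
    )
    DIC = (
        config.dic_surface
        + config.dic_gradient * (1.0 - np.exp(-z / config.dic_efold))
        + 0.6 * config.o2_seasonal_amp * bump * subsurface
    )
    TA = config.ta_surface + config.ta_gradient * (1.0 - np.exp(-z / config.ta_efold))
    NO3 = 0.5 + 34.0 * (1.0 - np.exp(-z / config.nitracline_depth))
    NH4 = np.full((1, nz, 1, 1), 0.05)
    PO4 = 0.2 + 2.6 * (1.0 - np.exp(-z / 120.0))
    SiO3 = 2.0 + 58.0 * (1.0 - np.exp(-z / 140.0))
    NPP = (
        config.productivity_multiplier
        * 4.0
        * (1.0 + 0.3 * seas_t)
        * np.exp(-z / 25.0)
    )
    RESP = 2.0 * np.exp(-(((z - 80.0) / 70.0) ** 2)) * (1.0 + 0.2 * bump)

    fields = {}
    for name, arr in (
        ("T", T), ("S", S), ("O2", O2), ("DIC", DIC), ("TA", TA),
        ("NO3", NO3), ("NH4", NH4), ("PO4", PO4), ("SiO3", SiO3),
        ("NPP", NPP), ("RESP", RESP),
    ):
        fields[name] = np.broadcast_to(arr, (nt, nz, ny, nx)).astype(float).copy()

    # circulation: mean alongshore + offshore drift plus seeded eddies
    rng = np.random.default_rng(config.seed)
    dx_m = config.dx_km * 1000.0
    u = np.full((nt, nz, ny, nx), config.u_offshore)
    v = np.full((nt, nz, ny, nx), config.v_alongshore)
    for t in range(nt):
        psi = gaussian_filter(rng.standard_normal((ny, nx)), config.eddy_smooth_cells)
        up = -np.gradient(psi, axis=0) / dx_m
        vp = np.gradient(psi, axis=1) / dx_m
        rms = np.sqrt(np.mean(up**2 + vp**2))
        scale = config.eddy_amplitude / rms if rms > 0 else 0.0
        taper = np.exp(-grid.z_centers / 300.0).reshape(nz, 1, 1)
        u[t] += scale * up[None] * taper
        v[t] += scale * vp[None] * taper
    fields["u"] = u
    fields["v"] = v
    return fields


def _plume_kernels(
    config: SynthConfig, grid: Grid, rec_lon: float, rec_lat: float, depth: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(horizontal kernel, downstream-shifted kernel, discharge-depth vertical
    kernel, respiration-band vertical kernel); all peak at 1."""
    lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
    dx_km = (lon2d - rec_lon) * KM_PER_DEG_LAT * np.cos(np.radians(rec_lat))
    dy_km = (lat2d - rec_lat) * KM_PER_DEG_LAT

    def horiz(shift_km: float) -> np.ndarray:
        r = np.sqrt(dx_km**2 + ((dy_km - shift_km) / config.alongshore_stretch) ** 2)
        k = np.exp(-r / config.plume_efold_km)
        k[grid.land_mask] = 0.0
        return k

    kh = horiz(0.0)
    kh_shift = horiz(config.downstream_shift_km * np.sign(config.v_alongshore))
    z = grid.z_centers
    kz_discharge = np.exp(-(((z - depth) / config.plume_sigma_z) ** 2))
    kz_resp = np.exp(-(((z - config.resp_center_depth) / config.resp_sigma_z) ** 2))
    return kh, kh_shift, kz_discharge, kz_resp


def generate(
    config: SynthConfig,
    scenario: Optional[EffluentResult] = None,
    label: Optional[str] = None,
) -> Tuple[OceanState, Grid]:
    """Background state plus load-linear plume anomalies for one scenario.

    Deterministic given (config, scenario, seed).  ``scenario=None`` (or one
    with all-zero DIN loads) returns the pure background.
    """
    grid = build_grid(config)
    time = _month_axis(config)
    fields = _background(config, grid, time)
    nt, nz = len(time), grid.nz
    ny, nx = grid.shape

    if scenario is not None:
        for row in scenario.rows:
            if not (
                grid.lon.min() <= row.lon <= grid.lon.max()
                and grid.lat.min() <= row.lat <= grid.lat.max()
            ):
                raise PlacementError(
                    f"outfall {row.plant_id} at ({row.lon:.3f}, {row.lat:.3f}) "
                    "falls outside the grid"
                )
            load = float(np.mean(np.atleast_1d(row.din_load())))  # kg DIN / d
            if load == 0.0:
                continue
            kh, kh_shift, kz_d, kz_r = _plume_kernels(
                config, grid, row.lon, row.lat, row.discharge_depth
            )
            kz_eu = np.exp(-grid.z_centers / 20.0) * (grid.z_centers <= config.euphotic_depth)
            nh4_anom = config.gain_nh4 * load * kz_d[:, None, None] * kh[None]
            npp_anom = config.gain_npp * load * kz_eu[:, None, None] * kh[None]
            resp_anom = (
                config.resp_fraction
                * config.gain_npp
                * load
                * kz_r[:, None, None]
                * kh_shift[None]
            )
            fields["NH4"] += nh4_anom[None]
            fields["NPP"] += npp_anom[None]
            fields["RESP"] += resp_anom[None]
            o2_anom = config.o2_to_c * config.accumulation_days * resp_anom
            fields["O2"] -= o2_anom[None]
            fields["DIC"] += config.accumulation_days * resp_anom[None]

    # flag land / below-bottom as missing, with one shared pattern
    wet = grid.wet_mask3d()
    mask4 = np.broadcast_to(wet[None], (nt, nz, ny, nx))
    for name, arr in fields.items():
        if name not in ("u", "v"):
            np.maximum(arr, 0.0, out=arr)  # documented non-negativity floor
        arr[~mask4] = np.nan

    state = OceanState(
        time=time,
        fields=fields,
        scenario_label=label or (scenario.label if scenario is not None else "BACKGROUND"),
        attrs={"seed": str(config.seed)},
    )
    return state, grid


def make_fixture_pair(
    config: SynthConfig,
    anth_result: Optional[EffluentResult] = None,
) -> Tuple[OceanState, OceanState, Grid]:
    """(ANTH state, CTRL state, grid) sharing the identical background/eddy
    realization, so ANTH - CTRL isolates the anthropogenic forcing."""
    from eutroscen.effluent import ScenarioSpec, apply_scenario

    records = default_outfalls(config)
    if anth_result is None:
        anth_result = apply_scenario(records, ScenarioSpec(label="ANTH"))
    anth_state, grid = generate(config, anth_result, label="ANTH")
    ctrl_state, _ = generate(config, None, label="CTRL")
    return anth_state, ctrl_state, grid
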