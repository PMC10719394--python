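"""Offshore ammonium transport across a target isobath (default 200 m).

The isobath section is the staircase of grid-cell faces separating columns
shallower than the target depth from columns at least as deep; the face
normal points toward the deeper (offshore) side, so positive flux is
shelf -> offshore.  Fluxes use monthly mean velocity and NH4, both
interpolated to the face as the arithmetic mean of the two adjacent cell
centers, over the 0 - target-depth window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from eutroscen.grid import EARTH_RADIUS_M, Grid, OceanState


class SectionError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


@dataclass
class Face:
    """One cell face on the isobath staircase.

    ``orientation`` is "u" for a face between x-neighbours (normal along x)
    or "v" for a face between y-neighbours (normal along y).
    ``normal_sign`` = +-1 such that normal_sign * velocity_component points
    from the shallow to the deep side.
    """

    j_shallow: int
    i_shallow: int
    j_deep: int
    i_deep: int
    orientation: str
    normal_sign: int
    length_m: float


@dataclass
class IsobathSection:
    target_depth: float
    faces: List[Face]

    def __len__(self) -> int:
        return len(self.faces)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "j_shallow": f.j_shallow,
                    "i_shallow": f.i_shallow,
                    "j_deep": f.j_deep,
                    "i_deep": f.i_deep,
                    "orientation": f.orientation,
                    "normal_sign": f.normal_sign,
                    "length_m": f.length_m,
                }
                for f in self.faces
            ]
        )


@dataclass
class FluxProfile:
    """Per-layer alongshore-aggregated transport across the section."""

    z_centers: np.ndarray
    layer_thickness: np.ndarray  # window-clipped, m
    transport_mol_s: np.ndarray  # (nz_window,), positive = offshore
    per_area_mmol_m2_s: np.ndarray
    section_area_m2: np.ndarray  # per layer
    scenario_label: str = ""
    period_label: str = ""

    def total_mol_s(self) -> float:
        return float(np.nansum(self.transport_mol_s))

    def volume_normalized_mmol_m3_d(self, adjacent_volume_m3: float) -> np.ndarray:
        """Transport divided by a section-adjacent volume, in mmol m-3 d-1."""
        return self.transport_mol_s * 1000.0 * 86400.0 / adjacent_volume_m3


def _face_lengths(grid: Grid) -> Tuple[np.ndarray, np.ndarray]:
    """(dy per row for u-faces, dx per row for v-faces) in meters."""
    dlat = np.abs(np.gradient(grid.lat))
    dlon = np.abs(np.gradient(grid.lon))
    dy = np.radians(dlat) * EARTH_RADIUS_M  # length of a meridional step per row
    dx = np.radians(dlon)[None, :] * EARTH_RADIUS_M * np.cos(np.radians(grid.lat))[:, None]
    return dy, dx


def extract_isobath(grid: Grid, target: float = 200.0) -> IsobathSection:
    """Staircase of faces where bathymetry crosses the target depth.

    Every face separates an ocean cell with bathymetry < target from an ocean
    cell with bathymetry >= target.  Deterministic; faces are unique by
    construction (each ordered neighbour pair appears once).
    """
    b = grid.bathymetry
    ocean = ~grid.land_mask
    shallow = ocean & (b < target)
    deep = ocean & (b >= target)
    if not shallow.any() or not deep.any():
        raise SectionError(f"bathymetry does not cross {target} m within the domain")
    dy, dx = _face_lengths(grid)
    faces: List[Face] = []
    ny, nx = grid.shape
    # x-direction neighbours -> "u" faces
    for j in range(ny):
        for i in range(nx - 1):
            a, c = (j, i), (j, i + 1)
            if shallow[a] and deep[c]:
                faces.append(Face(j, i, j, i + 1, "u", +1, dy[j]))
            elif deep[a] and shallow[c]:
                faces.append(Face(j, i + 1, j, i, "u", -1, dy[j]))
    # y-direction neighbours -> "v" faces
    for j in range(ny - 1):
        for i in range(nx):
            a, c = (j, i), (j + 1, i)
            if shallow[a] and deep[c]:
                faces.append(Face(j, i, j + 1, i, "v", +1, dx[j, i]))
            elif deep[a] and shallow[c]:
                faces.append(Face(j + 1, i, j, i, "v", -1, dx[j, i]))
    if not faces:
        raise SectionError(f"no shallow/deep cell adjacency at {target} m")
    return IsobathSection(target_depth=target, faces=faces)


def section_flux(
    state: OceanState,
    grid: Grid,
    section: IsobathSection,
    window: Optional[Tuple[float, float]] = None,
    period_label: str = "",
) -> FluxProfile:
    """Ammonium transport per layer across the section, time-averaged.

    flux(face, layer) = normal velocity x NH4 x face length x layer
    thickness, with velocity and NH4 arithmetic means of the two adjacent
    cell centers; positive = shelf -> offshore.  Units: NH4 mmol m-3 and
    velocity m s-1 give mmol s-1, reported as mol s-1.
    """
    window = window or (0.0, section.target_depth)
    edges = grid.z_edges()
    lo = np.clip(edges[:-1], *window)
    hi = np.clip(edges[1:], *window)
    thick = hi - lo
    zsel = np.nonzero(thick > 0)[0]
    nz = zsel.size
    nt = len(state.time)
    total = np.zeros(nz)
    area = np.zeros(nz)
    u = state["u"]
    v = state["v"]
    nh4 = state["NH4"]
    for f in section.faces:
        vel4 = u if f.orientation == "u" else v
        a = (slice(None), zsel, f.j_shallow, f.i_shallow)
        c = (slice(None), zsel, f.j_deep, f.i_deep)
        vel_face = 0.5 * (vel4[a] + vel4[c])  # (nt, nz)
        nh4_face = 0.5 * (nh4[a] + nh4[c])
        wet = np.isfinite(vel_face) & np.isfinite(nh4_face)
        # a face layer is wet if the shallow side has water at that level
        shallow_wet = grid.z_centers[zsel] < grid.bathymetry[f.j_shallow, f.i_shallow]
        need = np.broadcast_to(shallow_wet, (nt, nz))
        if np.any(need & ~wet):
            raise IntegrityError(
                f"missing velocity/NH4 at wet face layers near cell "
                f"({f.j_shallow}, {f.i_shallow})"
            )
        contrib = np.where(wet, f.normal_sign * vel_face * nh4_face, 0.0)
        total += contrib.mean(axis=0) * f.length_m * thick[zsel]
        area += shallow_wet * f.length_m * thick[zsel]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_area = np.where(area > 0, total / area, np.nan)
    return FluxProfile(
        z_centers=grid.z_centers[zsel],
        layer_thickness=thick[zsel],
        transport_mol_s=total / 1000.0,
        per_area_mmol_m2_s=per_area,
        section_area_m2=area,
        scenario_label=state.scenario_label,
        period_label=period_label,
    )


def flux_change(profile_a: FluxProfile, profile_b: FluxProfile) -> FluxProfile:
    """Layerwise difference a - b of two flux profiles on the same section."""
    if profile_a.z_centers.shape != profile_b.z_centers.shape or not np.allclose(
        profile_a.z_centers, profile_b.z_centers
    ):
        raise IntegrityError("flux profiles are on different sections/windows")
    return FluxProfile(
        z_centers=profile_a.z_centers,
        layer_thickness=profile_a.layer_thickness,
        transport_mol_s=profile_a.transport_mol_s - profile_b.transport_mol_s,
        per_area_mmol_m2_s=profile_a.per_area_mmol_m2_s - profile_b.per_area_mmol_m2_s,
        section_area_m2=profile_a.section_area_m2,
        scenario_label=f"{profile_a.scenario_label} - {profile_b.scenario_label}",
        period_label=profile_a.period_label,
    )
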