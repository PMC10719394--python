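"""Vertical-thickness habitat-capacity metrics for aerobic taxa and calcifiers.

Two criteria are evaluated per water column inside a 0-200 m window:

* aerobic: Metabolic Index Phi = A0 * pO2 * exp[(E0/kB) (1/T - 1/Tref)]
  with Phi / Phi_crit >= 1 marking viable habitat.  pO2 comes from the O2
  concentration via the Garcia & Gordon (1992) Benson-Krause solubility fit.
* calcifier: aragonite saturation state Omega_Ar >= theta (default 1.4, the
  sublethal-stress threshold for calcifying zooplankton such as pteropods).

Habitat thickness is the vertical measure of the set where the criterion
quantity, interpolated linearly between layer centers, meets the threshold;
non-contiguous intervals are summed.  Late-summer (Aug-Oct) means, % change
against a reference scenario and areal-extent histograms mirror the standard
change-assessment presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from eutroscen.carbonate import CarbonateParams, omega_field
from eutroscen.grid import Grid, OceanState, REFERENCE_DENSITY, nanmean_quiet

K_BOLTZMANN_EV = 8.617333e-5  # eV / K
ATM_KPA = 101.325
X_O2 = 0.20946  # mole fraction of O2 in dry air


class DomainError(ValueError):
    pass


@dataclass
class MetabolicTraits:
    """Species traits for the Metabolic Index.

    The shipped defaults are synthetic placeholder values for testing the
    machinery; real species traits (e.g. northern anchovy) must be supplied
    from the trait literature, in the same pO2 unit convention (kPa).
    """

    A0: float = 1.0  # kPa^-1, hypoxic tolerance (body-mass scaling absorbed)
    E0: float = 0.4  # eV, temperature sensitivity
    T_ref: float = 288.15  # K
    Phi_crit: float = 8.0
    species_label: str = "synthetic-placeholder"

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise DomainError("A0 must be positive")


def o2_saturation(T, S) -> np.ndarray:
    """O2 solubility at 1 atm moist air, umol kg-1 (Garcia & Gordon 1992,
    Benson & Krause coefficients)."""
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    Ts = np.log((298.15 - T) / (273.15 + T))
    a = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
    b = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
    c0 = -2.75915e-7
    lnC = (
        a[0] + a[1] * Ts + a[2] * Ts**2 + a[3] * Ts**3 + a[4] * Ts**4 + a[5] * Ts**5
        + S * (b[0] + b[1] * Ts + b[2] * Ts**2 + b[3] * Ts**3)
        + c0 * S**2
    )
    return np.exp(lnC)


def po2_from_o2(O2, T, S, depth=0.0, reference_density: float = REFERENCE_DENSITY) -> np.ndarray:
    """O2 partial pressure (kPa) from concentration (mmol m-3).

    pO2 = xO2 * 1 atm * O2 / O2_sat(T, S); air-saturated water therefore maps
    to the atmospheric O2 partial pressure (~21.2 kPa), without the small
    water-vapour correction.  The hydrostatic pressure effect on solubility is
    neglected over the 0-200 m evaluation window; ``depth`` is accepted for
    interface compatibility.
    """
    O2 = np.asarray(O2, dtype=float)
    if np.any(O2[np.isfinite(O2)] < 0):
        raise DomainError("negative O2 concentration")
    o2_umolkg = O2 * (1000.0 / reference_density)
    return X_O2 * ATM_KPA * o2_umolkg / o2_saturation(T, S)


def metabolic_index(pO2, T_kelvin, traits: MetabolicTraits) -> np.ndarray:
    """Phi = A0 * pO2 * exp[(E0/kB) (1/T - 1/Tref)]; zero iff pO2 is zero."""
    pO2 = np.asarray(pO2, dtype=float)
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T[np.isfinite(T)] <= 0):
        raise DomainError("temperature must be positive kelvin")
    if np.any(pO2[np.isfinite(pO2)] < 0):
        raise DomainError("pO2 must be non-negative")
    return traits.A0 * pO2 * np.exp((traits.E0 / K_BOLTZMANN_EV) * (1.0 / T - 1.0 / traits.T_ref))


def habitat_thickness(
    criterion: np.ndarray,
    z_centers: np.ndarray,
    z_thickness: np.ndarray,
    bathymetry: np.ndarray,
    threshold: float = 1.0,
    window: Tuple[float, float] = (0.0, 200.0),
) -> np.ndarray:
    """Thickness (m) of the window where the criterion quantity >= threshold.

    ``criterion`` has shape (nz, ...) on layer centers (NaN below bottom /
    on land); ``bathymetry`` broadcasts over the trailing dims.  The quantity
    is linear between adjacent centers, constant above the first center and
    below the last wet center; disjoint intervals are summed.  Columns with no
    wet layer return NaN.
    """
    q = np.asarray(criterion, dtype=float)
    zc = np.asarray(z_centers, dtype=float)
    bathy = np.broadcast_to(np.asarray(bathymetry, dtype=float), q.shape[1:])
    wtop, wbot_nominal = window
    wbot = np.minimum(wbot_nominal, bathy)
    wet = np.isfinite(q) & (zc.reshape((-1,) + (1,) * (q.ndim - 1)) < bathy)
    nwet = wet.sum(axis=0)
    met = q >= threshold

    thickness = np.zeros(q.shape[1:], dtype=float)
    # segment above the first layer center: constant value q[0]
    seg_len = np.clip(np.minimum(zc[0], wbot) - wtop, 0.0, None)
    thickness += np.where(wet[0] & met[0], seg_len, 0.0)
    # interior segments between adjacent centers
    for i in range(len(zc) - 1):
        z1, z2 = zc[i], zc[i + 1]
        valid = wet[i] & wet[i + 1]
        a = np.maximum(z1, wtop)
        b = np.minimum(z2, wbot)
        length = np.clip(b - a, 0.0, None)
        q1 = np.where(valid, q[i], 0.0)
        q2 = np.where(valid, q[i + 1], 0.0)
        both = met[i] & met[i + 1] & valid
        neither = (~met[i]) & (~met[i + 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            zx = z1 + (threshold - q1) * (z2 - z1) / np.where(q2 == q1, np.inf, q2 - q1)
        # met interval endpoints inside [z1, z2]
        m_lo = np.where(met[i], z1, zx)
        m_hi = np.where(met[i + 1], z2, zx)
        part = np.clip(np.minimum(m_hi, b) - np.maximum(m_lo, a), 0.0, None)
        contrib = np.where(both, length, np.where(neither, 0.0, part))
        thickness += np.where(valid, contrib, 0.0)
        # bottom extension for columns whose last wet center is layer i
        last_here = wet[i] & ~wet[i + 1]
        ext = np.clip(wbot - np.maximum(z1, wtop), 0.0, None)
        thickness += np.where(last_here & met[i], ext, 0.0)
    # columns whose last wet center is the deepest layer
    last_is_bottom = wet[-1]
    ext = np.clip(wbot - np.maximum(zc[-1], wtop), 0.0, None)
    thickness += np.where(last_is_bottom & met[-1], ext, 0.0)
    span = np.clip(wbot - wtop, 0.0, None)
    thickness = np.minimum(thickness, span)
    return np.where(nwet > 0, thickness, np.nan)


def aerobic_criterion(state: OceanState, traits: MetabolicTraits) -> np.ndarray:
    """Phi / Phi_crit on the full (time, depth, y, x) grid."""
    po2 = po2_from_o2(state["O2"], state["T"], state["S"])
    phi = metabolic_index(po2, np.asarray(state["T"], dtype=float) + 273.15, traits)
    return phi / traits.Phi_crit


@dataclass
class AreaDistribution:
    """Histogram of areal extent (km^2) per % change bin."""

    bin_edges: np.ndarray
    area_km2: np.ndarray
    area_above_10pct: float = 0.0
    area_above_20pct: float = 0.0
    area_below_minus10pct: float = 0.0
    area_below_minus20pct: float = 0.0


@dataclass
class HabitatChangeReport:
    """Late-summer habitat thickness change for one scenario vs a reference."""

    metric: str
    scenario_label: str
    reference_label: str
    thickness_scenario: np.ndarray  # (ny, nx) Aug-Oct mean, m
    thickness_reference: np.ndarray
    pct_change: np.ndarray  # (ny, nx), NaN where masked
    distribution: AreaDistribution
    params: Dict[str, float] = field(default_factory=dict)


def _late_summer_mean(time_index, fields: np.ndarray) -> np.ndarray:
    months = np.asarray(time_index.month)
    sel = np.isin(months, (8, 9, 10))
    if not sel.any():
        raise DomainError("no August-October timesteps in the state")
    return nanmean_quiet(fields[sel], axis=0)


def habitat_change_report(
    scenario: OceanState,
    reference: OceanState,
    grid: Grid,
    traits: Optional[MetabolicTraits] = None,
    theta_omega: float = 1.4,
    metrics: Sequence[str] = ("aerobic", "calcifier"),
    min_reference_thickness: float = 1.0,
    mask_shallower_than: float = 200.0,
    bin_width_pct: float = 5.0,
    carbonate_params: Optional[CarbonateParams] = None,
) -> Dict[str, HabitatChangeReport]:
    """Aug-Oct mean habitat thickness for scenario and reference, % change
    maps and areal-extent distributions.

    Columns with bathymetry < ``mask_shallower_than`` (default 200 m, to
    highlight pelagic environments) or with reference thickness below
    ``min_reference_thickness`` (denominator floor) are masked.
    """
    if len(scenario.time) != len(reference.time) or scenario["O2"].shape != reference["O2"].shape:
        raise DomainError("scenario and reference states do not share grid/time axes")
    traits = traits or MetabolicTraits()
    months = np.asarray(scenario.time.month)
    sel = np.isin(months, (8, 9, 10))
    if not sel.any():
        raise DomainError("no August-October timesteps in the state")

    out: Dict[str, HabitatChangeReport] = {}
    for metric in metrics:
        thick = {}
        for name, st in (("scenario", scenario), ("reference", reference)):
            sub = OceanState(
                time=st.time[sel],
                fields={k: v[sel] for k, v in st.fields.items()},
                scenario_label=st.scenario_label,
            )
            if metric == "aerobic":
                crit = aerobic_criterion(sub, traits)
                threshold = 1.0
            elif metric == "calcifier":
                crit = omega_field(sub, grid, carbonate_params)
                threshold = theta_omega
            else:
                raise DomainError(f"unknown habitat metric {metric!r}")
            per_time = np.stack(
                [
                    habitat_thickness(
                        crit[t], grid.z_centers, grid.z_thickness, grid.bathymetry,
                        threshold=threshold,
                    )
                    for t in range(crit.shape[0])
                ]
            )
            thick[name] = nanmean_quiet(per_time, axis=0)
        masked = (grid.bathymetry < mask_shallower_than) | grid.land_mask
        ref_t = thick["reference"]
        denom_ok = ref_t >= min_reference_thickness
        pct = np.where(
            ~masked & denom_ok & np.isfinite(ref_t),
            100.0 * (thick["scenario"] - ref_t) / np.where(denom_ok, ref_t, np.nan),
            np.nan,
        )
        out[metric] = HabitatChangeReport(
            metric=metric,
            scenario_label=scenario.scenario_label,
            reference_label=reference.scenario_label,
            thickness_scenario=thick["scenario"],
            thickness_reference=ref_t,
            pct_change=pct,
            distribution=area_distribution(pct, grid, bin_width_pct),
            params={
                "theta_omega": theta_omega,
                "min_reference_thickness": min_reference_thickness,
                "mask_shallower_than": mask_shallower_than,
            },
        )
    return out


def area_distribution(pct_change: np.ndarray, grid: Grid, bin_width: float = 5.0) -> AreaDistribution:
    """Areal extent (km^2) per % change bin, plus +-10% / +-20% exceedance areas."""
    area_km2 = grid.cell_area / 1e6
    valid = np.isfinite(pct_change)
    vals = pct_change[valid]
    areas = area_km2[valid]
    if vals.size:
        lim = max(20.0, np.ceil(np.max(np.abs(vals)) / bin_width) * bin_width)
    else:
        lim = 20.0
    edges = np.arange(-lim, lim + bin_width / 2, bin_width)
    hist = np.zeros(edges.size - 1)
    idx = np.clip(np.digitize(vals, edges) - 1, 0, edges.size - 2)
    np.add.at(hist, idx, areas)
    return AreaDistribution(
        bin_edges=edges,
        area_km2=hist,
        area_above_10pct=float(areas[vals > 10.0].sum()),
        area_above_20pct=float(areas[vals > 20.0].sum()),
        area_below_minus10pct=float(areas[vals < -10.0].sum()),
        area_below_minus20pct=float(areas[vals < -20.0].sum()),
    )
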