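"""Seawater carbonate-system solver: pH (total scale), carbonate ion, aragonite
saturation state and pCO2 from DIC, total alkalinity, T, S, pressure, phosphate
and silicate.

Dialect
-------
The classic CO2SYS recommended constant set: K1/K2 of Lueker et al. (2000,
total scale), bisulfate of Dickson (1990a), fluoride of Dickson & Riley (1979),
total boron of Uppström (1974), water/phosphoric/silicic constants of Millero
(1995, seawater scale), aragonite solubility of Mucci (1983) with [Ca2+]
proportional to salinity, CO2 solubility of Weiss (1974).  Pressure corrections
use the Millero (1995) molal-volume/compressibility forms; following the CO2SYS
procedure, constants are assembled on the seawater scale, pressure-corrected,
then converted to the total scale with the pressure-corrected HSO4-/HF
constants.  In-situ pressure is approximated as depth(m)/10 dbar.

The pH root of ``TA(pH; DIC, totals) = TA_input`` is found by a safeguarded
Newton iteration (bisection fallback) on the bracket pH in [2, 12], vectorized
over arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from eutroscen.grid import Grid, OceanState, REFERENCE_DENSITY

R_GAS = 83.1451  # cm3 bar mol-1 K-1


class ConvergenceError(RuntimeError):
    """pH iteration failed to converge inside the bracket."""


@dataclass
class CarbonateParams:
    """Solver configuration.  Only the documented dialect is shipped; the
    fields exist so the output metadata names the choices explicitly."""

    k1k2: str = "Lueker2000"
    bisulfate: str = "Dickson1990"
    borate: str = "Uppstrom1974"
    ph_scale: str = "total"
    pressure_correction: bool = True
    reference_density: float = REFERENCE_DENSITY  # for mmol/m3 <-> umol/kg

    def __post_init__(self) -> None:
        if (self.k1k2, self.bisulfate, self.borate, self.ph_scale) != (
            "Lueker2000",
            "Dickson1990",
            "Uppstrom1974",
            "total",
        ):
            raise ValueError("unsupported carbonate constant dialect")


@dataclass
class CarbonateResult:
    """Solved carbonate state (arrays broadcast to the input shape)."""

    pH_total: np.ndarray
    CO3: np.ndarray  # umol/kg
    omega_ar: np.ndarray
    pCO2: np.ndarray  # uatm
    out_of_range: np.ndarray  # True where inputs were outside the stated domain


def equilibrium_constants(T_c, S, P_dbar, pressure_correction: bool = True) -> Dict[str, np.ndarray]:
    """All constants on the total pH scale in mol/kg-sw (Ksp in mol2 kg-2).

    Also returns the totals TB, TS, TF, Ca (mol/kg) and the free/total
    conversion factor at pressure.
    """
    T_c = np.asarray(T_c, dtype=float)
    S = np.asarray(S, dtype=float)
    P_bar = np.asarray(P_dbar, dtype=float) / 10.0
    T = T_c + 273.15
    lnT = np.log(T)
    sqrtS = np.sqrt(np.maximum(S, 0.0))
    IonS = 19.924 * S / (1000.0 - 1.005 * S)
    sqrtI = np.sqrt(np.maximum(IonS, 0.0))

    TB = 0.0004157 * S / 35.0  # Uppstrom 1974
    TS = (0.14 / 96.062) * (S / 1.80655)
    TF = (0.000067 / 18.998) * (S / 1.80655)
    Ca = (0.02128 / 40.087) * (S / 1.80655)

    # --- HSO4- (Dickson 1990a), free scale, then mol/kg-sw
    lnKS = (
        -4276.1 / T + 141.328 - 23.093 * lnT
        + (-13856.0 / T + 324.57 - 47.986 * lnT) * sqrtI
        + (35474.0 / T - 771.54 + 114.723 * lnT) * IonS
        - 2698.0 / T * IonS**1.5
        + 1776.0 / T * IonS**2
    )
    KS = np.exp(lnKS) * (1.0 - 0.001005 * S)

    # --- HF (Dickson & Riley 1979), free scale, mol/kg-sw
    lnKF = 1590.2 / T - 12.641 + 1.525 * sqrtI
    KF = np.exp(lnKF) * (1.0 - 0.001005 * S)

    sws_to_tot_0 = (1.0 + TS / KS) / (1.0 + TS / KS + TF / KF)

    # --- K1, K2 (Lueker et al. 2000), total scale -> seawater scale
    pK1 = 3633.86 / T - 61.2172 + 9.67770 * lnT - 0.011555 * S + 0.0001152 * S**2
    pK2 = 471.78 / T + 25.9290 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S**2
    K1 = 10.0 ** (-pK1) / sws_to_tot_0
    K2 = 10.0 ** (-pK2) / sws_to_tot_0

    # --- KB (Dickson 1990b), total scale -> seawater scale
    lnKB = (
        (-8966.90 - 2890.53 * sqrtS - 77.942 * S + 1.728 * S * sqrtS - 0.0996 * S**2) / T
        + 148.0248 + 137.1942 * sqrtS + 1.62142 * S
        + (-24.4344 - 25.085 * sqrtS - 0.2474 * S) * lnT
        + 0.053105 * sqrtS * T
    )
    KB = np.exp(lnKB) / sws_to_tot_0

    # --- KW (Millero 1995), seawater scale
    lnKW = (
        148.9802 - 13847.26 / T - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqrtS
        - 0.01615 * S
    )
    KW = np.exp(lnKW)

    # --- phosphoric acid (Yao & Millero / Millero 1995), seawater scale
    lnKP1 = (
        -4576.752 / T + 115.525 - 18.453 * lnT
        + (-106.736 / T + 0.69171) * sqrtS
        + (-0.65643 / T - 0.01844) * S
    )
    lnKP2 = (
        -8814.715 / T + 172.0883 - 27.927 * lnT
        + (-160.340 / T + 1.3566) * sqrtS
        + (0.37335 / T - 0.05778) * S
    )
    lnKP3 = (
        -3070.75 / T - 18.141
        + (17.27039 / T + 2.81197) * sqrtS
        + (-44.99486 / T - 0.09984) * S
    )
    KP1, KP2, KP3 = np.exp(lnKP1), np.exp(lnKP2), np.exp(lnKP3)

    # --- silicic acid (Millero 1995), seawater scale, mol/kg-H2O -> kg-sw
    lnKSi = (
        -8904.2 / T + 117.385 - 19.334 * lnT
        + (-458.79 / T + 3.5913) * sqrtI
        + (188.74 / T - 1.5998) * IonS
        + (-12.1652 / T + 0.07871) * IonS**2
    )
    KSi = np.exp(lnKSi) * (1.0 - 0.001005 * S)

    # --- CO2 solubility (Weiss 1974), mol kg-1 atm-1
    T100 = T / 100.0
    lnK0 = (
        -60.2409 + 93.4517 / T100 + 23.3585 * np.log(T100)
        + S * (0.023517 - 0.023656 * T100 + 0.0047036 * T100**2)
    )
    K0 = np.exp(lnK0)

    # --- aragonite solubility (Mucci 1983), mol2 kg-2
    log10KspA = (
        -171.945 - 0.077993 * T + 2903.293 / T + 71.595 * np.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqrtS
        - 0.10018 * S + 0.0059415 * S * sqrtS
    )
    KspA = 10.0**log10KspA

    if pressure_correction:
        def pcorr(K, dV, dK):
            return K * np.exp((-dV + 0.5 * dK * P_bar) * P_bar / (R_GAS * T))

        TC = T_c
        K1 = pcorr(K1, -25.5 + 0.1271 * TC, (-3.08 + 0.0877 * TC) / 1000.0)
        K2 = pcorr(K2, -15.82 - 0.0219 * TC, (1.13 - 0.1475 * TC) / 1000.0)
        KB = pcorr(KB, -29.48 + 0.1622 * TC - 0.002608 * TC**2, -2.84 / 1000.0)
        KW = pcorr(KW, -20.02 + 0.1119 * TC - 0.001409 * TC**2, (-5.13 + 0.0794 * TC) / 1000.0)
        KS = pcorr(KS, -18.03 + 0.0466 * TC + 0.000316 * TC**2, (-4.53 + 0.09 * TC) / 1000.0)
        KF = pcorr(KF, -9.78 - 0.009 * TC - 0.000942 * TC**2, (-3.91 + 0.054 * TC) / 1000.0)
        KP1 = pcorr(KP1, -14.51 + 0.1211 * TC - 0.000321 * TC**2, (-2.67 + 0.0427 * TC) / 1000.0)
        KP2 = pcorr(KP2, -23.12 + 0.1758 * TC - 0.002647 * TC**2, (-5.15 + 0.09 * TC) / 1000.0)
        KP3 = pcorr(KP3, -26.57 + 0.2020 * TC - 0.003042 * TC**2, (-4.08 + 0.0714 * TC) / 1000.0)
        KSi = pcorr(KSi, -29.48 + 0.1622 * TC - 0.002608 * TC**2, -2.84 / 1000.0)
        # aragonite: calcite correction (Ingle 1975 / Millero 1979) + 2.8 cm3/mol
        KspA = pcorr(KspA, -48.76 + 0.5304 * TC + 2.8, (-11.76 + 0.3692 * TC) / 1000.0)

    # convert the seawater-scale set to the total scale at pressure
    free_to_tot = 1.0 + TS / KS
    sws_to_tot = free_to_tot / (1.0 + TS / KS + TF / KF)
    for_total = sws_to_tot
    return {
        "K0": K0,
        "K1": K1 * for_total,
        "K2": K2 * for_total,
        "KB": KB * for_total,
        "KW": KW * for_total,
        "KP1": KP1 * for_total,
        "KP2": KP2 * for_total,
        "KP3": KP3 * for_total,
        "KSi": KSi * for_total,
        "KS": KS,
        "KF": KF,
        "KspA": KspA,
        "TB": TB,
        "TS": TS,
        "TF": TF,
        "Ca": Ca,
        "free_to_tot": free_to_tot,
    }


def alkalinity_from_ph(pH, DIC, PO4, SiO3, k) -> np.ndarray:
    """Total alkalinity (mol/kg) implied by pH (total scale) and DIC (mol/kg).

    Carbonate + borate + water + phosphate + silicate terms minus free H+,
    HSO4- and HF.
    """
    H = 10.0 ** (-np.asarray(pH, dtype=float))
    Hfree = H / k["free_to_tot"]
    denom_c = H * H + k["K1"] * H + k["K1"] * k["K2"]
    CAlk = DIC * k["K1"] * (H + 2.0 * k["K2"]) / denom_c
    BAlk = k["TB"] * k["KB"] / (k["KB"] + H)
    OH = k["KW"] / H
    denom_p = H**3 + k["KP1"] * H**2 + k["KP1"] * k["KP2"] * H + k["KP1"] * k["KP2"] * k["KP3"]
    PAlk = PO4 * (
        k["KP1"] * k["KP2"] * H + 2.0 * k["KP1"] * k["KP2"] * k["KP3"] - H**3
    ) / denom_p
    SiAlk = SiO3 * k["KSi"] / (k["KSi"] + H)
    HSO4 = k["TS"] / (1.0 + k["KS"] / Hfree)
    HF = k["TF"] / (1.0 + k["KF"] / Hfree)
    return CAlk + BAlk + OH + PAlk + SiAlk - Hfree - HSO4 - HF


def _solve_ph(TA, DIC, PO4, SiO3, k, tol_frac: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Safeguarded Newton/bisection for the pH root on [2, 12] (total scale)."""
    lo = np.full(np.shape(TA), 2.0)
    hi = np.full(np.shape(TA), 12.0)
    f_lo = alkalinity_from_ph(lo, DIC, PO4, SiO3, k) - TA
    f_hi = alkalinity_from_ph(hi, DIC, PO4, SiO3, k) - TA
    bad = ~((f_lo < 0) & (f_hi > 0))
    if np.any(bad & np.isfinite(TA) & np.isfinite(np.asarray(DIC, dtype=float))):
        n_bad = int(np.sum(bad & np.isfinite(TA)))
        raise ConvergenceError(
            f"no TA sign change on pH bracket [2, 12] for {n_bad} input point(s); "
            "inputs are likely far outside the seawater regime"
        )
    pH = np.full(np.shape(TA), 8.0)
    tol = np.abs(TA) * tol_frac
    for _ in range(max_iter):
        f = alkalinity_from_ph(pH, DIC, PO4, SiO3, k) - TA
        done = np.abs(f) <= tol
        if np.all(done | ~np.isfinite(f)):
            break
        lo = np.where(f < 0, pH, lo)
        hi = np.where(f > 0, pH, hi)
        # forward-difference derivative of the TA residual in pH
        eps = 1e-6
        df = (alkalinity_from_ph(pH + eps, DIC, PO4, SiO3, k) - (f + TA)) / eps
        with np.errstate(divide="ignore", invalid="ignore"):
            step = -f / df
        newton = pH + step
        inside = (newton > lo) & (newton < hi) & np.isfinite(newton)
        pH = np.where(inside, newton, 0.5 * (lo + hi))
    finite_in = (
        np.isfinite(TA)
        & np.isfinite(np.asarray(DIC, dtype=float))
        & np.isfinite(k["K1"])
    )
    return np.where(finite_in, pH, np.nan)


def solve_carbonate(
    DIC,
    TA,
    T,
    S,
    pressure_dbar=0.0,
    PO4=0.0,
    SiO3=0.0,
    params: Optional[CarbonateParams] = None,
) -> CarbonateResult:
    """Solve the carbonate system; DIC/TA/PO4/SiO3 in umol kg-1 (ueq for TA).

    Inputs outside S in [0, 45], T in [-2, 40] degC or nonpositive DIC/TA are
    flagged in ``out_of_range`` (result still computed where finite).
    Missing (NaN) inputs propagate to NaN outputs.
    """
    params = params or CarbonateParams()
    DIC, TA, T, S, P, PO4, SiO3 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (DIC, TA, T, S, pressure_dbar, PO4, SiO3))
    )
    oor = (S < 0) | (S > 45) | (T < -2) | (T > 40) | (DIC <= 0) | (TA <= 0)
    k = equilibrium_constants(T, S, P, params.pressure_correction)
    dic = DIC * 1e-6
    ta = TA * 1e-6
    po4 = PO4 * 1e-6
    sio3 = SiO3 * 1e-6
    pH = _solve_ph(ta, dic, po4, sio3, k)
    H = 10.0 ** (-pH)
    denom = H * H + k["K1"] * H + k["K1"] * k["K2"]
    CO3 = dic * k["K1"] * k["K2"] / denom  # mol/kg
    CO2star = dic * H * H / denom
    omega = CO3 * k["Ca"] / k["KspA"]
    pCO2 = CO2star / k["K0"] * 1e6  # uatm
    return CarbonateResult(
        pH_total=pH,
        CO3=CO3 * 1e6,
        omega_ar=omega,
        pCO2=pCO2,
        out_of_range=oor,
    )


def omega_field(
    state: OceanState, grid: Grid, params: Optional[CarbonateParams] = None
) -> np.ndarray:
    """Aragonite saturation state on the full (time, depth, y, x) grid.

    Concentration inputs in mmol m-3 (TA meq m-3) are converted to umol kg-1
    with the configured reference density; in-situ pressure is depth/10 dbar
    per meter of depth (i.e. depth in dbar).  Missing inputs give missing
    output.
    """
    params = params or CarbonateParams()
    rho = params.reference_density / 1000.0  # kg/L
    conv = 1.0 / rho  # mmol/m3 -> umol/kg
    nt = len(state.time)
    shape = state["DIC"].shape
    pressure = np.broadcast_to(grid.z_centers[None, :, None, None], shape)
    out = np.full(shape, np.nan)
    wet = np.isfinite(state["DIC"])
    # solve one time slab at a time to bound peak memory
    for t in range(nt):
        w = wet[t]
        if not w.any():
            continue
        res = solve_carbonate(
            DIC=state["DIC"][t][w] * conv,
            TA=state["TA"][t][w] * conv,
            T=state["T"][t][w],
            S=state["S"][t][w],
            pressure_dbar=pressure[t][w],
            PO4=state["PO4"][t][w] * conv,
            SiO3=state["SiO3"][t][w] * conv,
            params=params,
        )
        slab = np.full(w.shape, np.nan)
        slab[w] = res.omega_ar
        out[t] = slab
    return out


def ph_field(state: OceanState, grid: Grid, params: Optional[CarbonateParams] = None) -> np.ndarray:
    """pH (total scale) companion to :func:`omega_field`."""
    params = params or CarbonateParams()
    conv = 1000.0 / params.reference_density
    shape = state["DIC"].shape
    pressure = np.broadcast_to(grid.z_centers[None, :, None, None], shape)
    out = np.full(shape, np.nan)
    wet = np.isfinite(state["DIC"])
    for t in range(len(state.time)):
        w = wet[t]
        if not w.any():
            continue
        res = solve_carbonate(
            DIC=state["DIC"][t][w] * conv,
            TA=state["TA"][t][w] * conv,
            T=state["T"][t][w],
            S=state["S"][t][w],
            pressure_dbar=pressure[t][w],
            PO4=state["PO4"][t][w] * conv,
            SiO3=state["SiO3"][t][w] * conv,
            params=params,
        )
        slab = np.full(w.shape, np.nan)
        slab[w] = res.pH_total
        out[t] = slab
    return out
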