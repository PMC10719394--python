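"""Per-outfall effluent mass balance for DIN management and potable recycling.

The mass balance treats potable recycling as a diversion of a fraction ``r`` of
the effluent through reverse osmosis: a fraction ``rho`` (recovery, default
0.8) of the diverted volume leaves the system as potable permeate, the rest
returns to the outfall as concentrate.  A constituent with rejection
efficiency ``eta`` keeps the fraction ``eta`` of its diverted mass in the
concentrate; ``1 - eta`` leaves with the permeate.  Hence for original load
``M`` and flow ``Q``::

    final_flow = Q * (1 - rho * r)
    final_load = (1 - r) * M + r * eta * M
    permeate_removed = r * (1 - eta) * M

DIN management caps each nitrogen species independently at its target
concentration (outfalls already below target are held constant) and is applied
before recycling.

Units: flows m3 d-1 (MGD accepted at read time), concentrations mg L-1
(alkalinity meq L-1, iron ug L-1); loads are flow x conc x 1e-3, i.e. kg d-1
for mg L-1 constituents, keq d-1 for alkalinity, g d-1 for iron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

M3D_PER_MGD = 3785.411784  # 1 US million gallons per day in m3/d

CONSTITUENTS = (
    "NH4",
    "NO3NO2",
    "PO4",
    "SiO3",
    "alkalinity",
    "organicC",
    "organicN",
    "organicP",
    "salt",
    "Fe",
)

#: membrane rejection efficiencies: fraction of diverted mass returned in the
#: concentrate (the complement leaves with the potable permeate)
DEFAULT_REJECTION: Dict[str, float] = {
    "NO3NO2": 0.85,
    "NH4": 0.95,
    "PO4": 0.95,
    "alkalinity": 0.95,
    "SiO3": 0.95,
    "organicC": 0.97,
    "organicN": 0.97,
    "organicP": 0.97,
    "salt": 1.0,
    "Fe": 1.0,
}

DEFAULT_RECOVERY = 0.8  # potable recovery efficiency rho

_CSV_COLS = {
    "NH4": "nh4_mgl",
    "NO3NO2": "no3no2_mgl",
    "PO4": "po4_mgl",
    "SiO3": "sio3_mgl",
    "alkalinity": "alk_meql",
    "organicC": "orgc_mgl",
    "organicN": "orgn_mgl",
    "organicP": "orgp_mgl",
    "salt": "salt_psu",
    "Fe": "fe_ugl",
}


class ParameterError(ValueError):
    """Invalid scenario parameter."""


@dataclass
class OutfallRecord:
    """One plant/outfall: flow (scalar or monthly series, m3 d-1) and concentrations."""

    plant_id: str
    lon: float
    lat: float
    discharge_depth: float
    flow: np.ndarray  # m3/d; shape () or (n_months,)
    conc: Dict[str, float]  # constituent -> mg/L (alk meq/L, Fe ug/L)

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        if np.any(self.flow <= 0):
            raise ParameterError(f"{self.plant_id}: flow must be positive")
        for c, v in self.conc.items():
            if np.any(np.asarray(v) < 0):
                raise ParameterError(f"{self.plant_id}: negative concentration for {c}")

    def load(self, constituent: str) -> np.ndarray:
        """Load = flow * conc * 1e-3 (kg/d for mg/L constituents)."""
        return self.flow * self.conc.get(constituent, 0.0) * 1e-3


@dataclass
class ScenarioSpec:
    """DIN targets + recycling fraction + membrane efficiencies."""

    label: str
    din_targets: Optional[Dict[str, float]] = None  # {NH4: mg/L, NO3NO2: mg/L}
    recycle_fraction: float = 0.0  # r
    recovery: float = DEFAULT_RECOVERY  # rho
    rejection: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REJECTION))
    zero_loads: bool = False  # CTRL: remove all outfall inputs

    def __post_init__(self) -> None:
        for name, v in (("recycle_fraction", self.recycle_fraction), ("recovery", self.recovery)):
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for c, eta in self.rejection.items():
            if not 0.0 <= eta <= 1.0:
                raise ParameterError(f"rejection[{c}] must be in [0, 1], got {eta}")
        if self.din_targets is not None:
            if set(self.din_targets) != {"NH4", "NO3NO2"}:
                raise ParameterError("din_targets must give both NH4 and NO3NO2")
            for c, t in self.din_targets.items():
                if t < 0:
                    raise ParameterError(f"negative DIN target for {c}")


@dataclass
class EffluentRow:
    """Mass-balance outcome for one outfall under one scenario."""

    plant_id: str
    lon: float
    lat: float
    discharge_depth: float
    original_flow: np.ndarray
    final_flow: np.ndarray
    final_conc: Dict[str, np.ndarray]
    final_load: Dict[str, np.ndarray]
    permeate_removed: Dict[str, np.ndarray]

    def din_load(self) -> np.ndarray:
        return self.final_load["NH4"] + self.final_load["NO3NO2"]


@dataclass
class EffluentResult:
    """All outfall rows for one scenario plus flow-weighted summaries."""

    label: str
    rows: List[EffluentRow]

    def total_flow(self) -> float:
        return float(np.mean(np.sum([np.atleast_1d(r.final_flow) for r in self.rows], axis=0)))

    def total_load(self, constituent: str) -> float:
        return float(
            np.mean(np.sum([np.atleast_1d(r.final_load[constituent]) for r in self.rows], axis=0))
        )

    def total_din_load(self) -> float:
        return self.total_load("NH4") + self.total_load("NO3NO2")

    def flow_weighted_conc(self, constituent: str) -> float:
        return self.total_load(constituent) / self.total_flow() * 1e3

    def din_flow_weighted(self) -> float:
        return self.flow_weighted_conc("NH4") + self.flow_weighted_conc("NO3NO2")


def apply_din_management(rec: OutfallRecord, targets: Optional[Mapping[str, float]]) -> OutfallRecord:
    """Cap each DIN species at its target concentration (min rule).

    Outfalls already at or below a target are held constant; other
    constituents and the flow are unchanged.  ``targets=None`` is the
    current-loading (ANTH) identity.
    """
    if targets is None:
        return replace(rec, conc=dict(rec.conc))
    conc = dict(rec.conc)
    for species in ("NH4", "NO3NO2"):
        if species not in targets:
            raise ParameterError(f"din_targets missing {species}")
        t = float(targets[species])
        if t < 0:
            raise ParameterError(f"negative DIN target for {species}")
        conc[species] = min(conc.get(species, 0.0), t)
    return replace(rec, conc=conc)


def apply_recycling(
    rec: OutfallRecord,
    recycle_fraction: float,
    recovery: float = DEFAULT_RECOVERY,
    rejection: Optional[Mapping[str, float]] = None,
) -> EffluentRow:
    """Reverse-osmosis mass balance for one outfall.

    Volume closure: discharged + potable-recovered = original, exactly.
    Mass closure per constituent: undiverted + concentrate + permeate =
    original load, exactly.
    """
    r, rho = float(recycle_fraction), float(recovery)
    if not 0.0 <= r <= 1.0 or not 0.0 <= rho <= 1.0:
        raise ParameterError("recycle fraction and recovery must be in [0, 1]")
    rejection = dict(DEFAULT_REJECTION) if rejection is None else dict(rejection)
    volume_factor = 1.0 - rho * r
    final_flow = rec.flow * volume_factor
    final_conc: Dict[str, np.ndarray] = {}
    final_load: Dict[str, np.ndarray] = {}
    removed: Dict[str, np.ndarray] = {}
    for c in CONSTITUENTS:
        eta = rejection.get(c, 1.0)
        load0 = rec.load(c)
        load = (1.0 - r) * load0 + r * eta * load0
        removed[c] = r * (1.0 - eta) * load0
        if volume_factor <= 0.0:
            if np.any(load > 0):
                raise ParameterError(
                    "rho * r = 1 leaves no discharge volume for a nonzero load"
                )
            final_conc[c] = np.zeros_like(load)
        else:
            final_conc[c] = load / final_flow * 1e3  # back to mg/L
        final_load[c] = load
    return EffluentRow(
        plant_id=rec.plant_id,
        lon=rec.lon,
        lat=rec.lat,
        discharge_depth=rec.discharge_depth,
        original_flow=rec.flow,
        final_flow=final_flow,
        final_conc=final_conc,
        final_load=final_load,
        permeate_removed=removed,
    )


def apply_scenario(records: Sequence[OutfallRecord], spec: ScenarioSpec) -> EffluentResult:
    """Management first, then recycling, for every outfall; CTRL zeroes loads."""
    rows = []
    for rec in records:
        if spec.zero_loads:
            zero = replace(rec, conc={c: 0.0 for c in rec.conc})
            row = apply_recycling(zero, 0.0, spec.recovery, spec.rejection)
        else:
            managed = apply_din_management(rec, spec.din_targets)
            row = apply_recycling(managed, spec.recycle_fraction, spec.recovery, spec.rejection)
        rows.append(row)
    return EffluentResult(label=spec.label, rows=rows)


def flow_weighted_summary(result: EffluentResult) -> Dict[str, float]:
    """Scenario totals and flow-weighted concentrations across all outfalls.

    Flow-weighted concentration = total load / total flow; DIN = NH4 + NO3NO2.
    Monthly series are time-averaged after the mass balance.
    """
    if not result.rows:
        raise ParameterError("empty outfall list")
    out = {"label": result.label, "total_flow_m3d": result.total_flow()}
    for c in CONSTITUENTS:
        out[f"load_{c}"] = result.total_load(c)
        out[f"fwconc_{c}"] = result.flow_weighted_conc(c)
    out["load_DIN"] = result.total_din_load()
    out["fwconc_DIN"] = out["fwconc_NH4"] + out["fwconc_NO3NO2"]
    return out


def default_scenario_specs() -> List[ScenarioSpec]:
    """The eight-scenario suite: CTRL, ANTH, and targets {7,13}/{1,4} x r in {0, .5, .9}.

    The two DIN-target tiers correspond to 50% and 85% reductions of typical
    secondary-effluent DIN via progressive nitrification-denitrification.
    """
    tiers = {"50": {"NH4": 7.0, "NO3NO2": 13.0}, "85": {"NH4": 1.0, "NO3NO2": 4.0}}
    specs = [
        ScenarioSpec(label="CTRL", zero_loads=True),
        ScenarioSpec(label="ANTH"),
    ]
    n = 0
    for tier in ("50", "85"):
        for r in (0.0, 0.5, 0.9):
            n += 1
            specs.append(
                ScenarioSpec(
                    label=f"Scenario {n}",
                    din_targets=dict(tiers[tier]),
                    recycle_fraction=r,
                )
            )
    return specs


def build_scenario_suite(
    records: Sequence[OutfallRecord], specs: Optional[Sequence[ScenarioSpec]] = None
) -> Dict[str, EffluentResult]:
    """One EffluentResult per scenario; labels must be unique."""
    specs = default_scenario_specs() if specs is None else list(specs)
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ParameterError("duplicate scenario labels")
    return {spec.label: apply_scenario(records, spec) for spec in specs}


def effluent_density(salt_psu: float, temperature_c: float = 20.0) -> float:
    """Approximate effluent density (kg m-3), linear in salinity and temperature.

    Reported for reference only; density/buoyancy changes are not propagated
    to plume geometry.
    """
    return 998.2 + 0.78 * salt_psu - 0.21 * (temperature_c - 20.0)


def read_outfalls(path) -> List[OutfallRecord]:
    """Read the outfall table CSV (columns per the documented schema).

    ``flow_m3d`` or ``flow_mgd`` is required; MGD is converted at read time.
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        if "flow_m3d" in df.columns and not pd.isna(row.get("flow_m3d")):
            flow = float(row["flow_m3d"])
        elif "flow_mgd" in df.columns:
            flow = float(row["flow_mgd"]) * M3D_PER_MGD
        else:
            raise ParameterError("outfall table needs flow_m3d or flow_mgd")
        conc = {c: float(row[col]) if col in df.columns else 0.0 for c, col in _CSV_COLS.items()}
        records.append(
            OutfallRecord(
                plant_id=str(row["plant_id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                discharge_depth=float(row["depth_m"]),
                flow=flow,
                conc=conc,
            )
        )
    if not records:
        raise ParameterError("empty outfall table")
    return records


def suite_summary_table(suite: Mapping[str, EffluentResult]) -> pd.DataFrame:
    """Scenario-by-scenario summary mirroring a management-scenario table:
    flow-weighted NH4, NO3+NO2, DIN (mg/L) and total DIN load (kg/d)."""
    rows = []
    for label, res in suite.items():
        s = flow_weighted_summary(res)
        rows.append(
            {
                "scenario": label,
                "nh4_mgl": s["fwconc_NH4"],
                "no3no2_mgl": s["fwconc_NO3NO2"],
                "din_mgl": s["fwconc_DIN"],
                "din_load_kgd": s["load_DIN"],
                "total_flow_m3d": s["total_flow_m3d"],
            }
        )
    return pd.DataFrame(rows)
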