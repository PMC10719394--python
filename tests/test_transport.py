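"""Cross-isobath section extraction and ammonium transport."""

import numpy as np
import pandas as pd
import pytest

from eutroscen.grid import Grid, OceanState
from eutroscen.transport import (
    IntegrityError,
    SectionError,
    extract_isobath,
    flux_change,
    section_flux,
)


def make_grid(bathy):
    ny, nx = bathy.shape
    dlat = 3.0 / 111.195
    return Grid(
        lon=-119.0 + np.arange(nx) * dlat,
        lat=33.0 + np.arange(ny) * dlat,
        z_centers=np.array([10.0, 50.0, 150.0]),
        z_thickness=np.array([20.0, 60.0, 140.0]),
        bathymetry=bathy,
        land_mask=np.zeros((ny, nx), dtype=bool),
    )


def make_state(grid, u=0.0, v=0.0, nh4=1.0, nt=2, seed=None):
    nz = grid.nz
    ny, nx = grid.shape
    wet = grid.wet_mask3d()
    fields = {}
    rng = np.random.default_rng(seed) if seed is not None else None
    for name in ("T", "S", "O2", "DIC", "TA", "NO3", "PO4", "SiO3", "NPP", "RESP"):
        fields[name] = np.full((nt, nz, ny, nx), 1.0)
    for name, val in (("u", u), ("v", v), ("NH4", nh4)):
        if rng is not None:
            arr = rng.normal(val, abs(val) * 0.3 + 0.5, size=(nt, nz, ny, nx))
            if name == "NH4":
                arr = np.abs(arr)
        else:
            arr = np.full((nt, nz, ny, nx), float(val))
        fields[name] = arr
    for name in fields:
        fields[name] = np.where(wet[None], fields[name], np.nan)
    time = pd.date_range("2016-01-15", periods=nt, freq="MS")
    return OceanState(time=time, fields=fields, scenario_label="test")


class TestExtractIsobath:
    def test_monotone_offshore_bathymetry_one_face_per_row(self):
        ny, nx = 5, 8
        bathy = np.tile(np.linspace(400, 50, nx), (ny, 1))  # deepens toward low x
        grid = make_grid(bathy)
        sec = extract_isobath(grid, 200.0)
        assert len(sec) == ny
        assert all(f.orientation == "u" for f in sec.faces)
        # normal points from the shallow (high-x) toward the deep (low-x) side
        assert all(f.normal_sign == -1 for f in sec.faces)

    def test_flat_domain_has_no_crossing(self):
        grid = make_grid(np.full((4, 4), 100.0))
        with pytest.raises(SectionError, match="cross"):
            extract_isobath(grid, 200.0)

    def test_bumpy_bathymetry_exhaustive_face_check(self):
        rng = np.random.default_rng(31)
        bathy = rng.uniform(50, 400, size=(10, 12))
        grid = make_grid(bathy)
        sec = extract_isobath(grid, 200.0)
        # every face separates shallow from deep
        for f in sec.faces:
            assert bathy[f.j_shallow, f.i_shallow] < 200.0
            assert bathy[f.j_deep, f.i_deep] >= 200.0
        # and every shallow/deep adjacency is present exactly once
        count = 0
        for j in range(10):
            for i in range(12):
                for dj, di in ((0, 1), (1, 0)):
                    j2, i2 = j + dj, i + di
                    if j2 >= 10 or i2 >= 12:
                        continue
                    pair = {bathy[j, i] < 200.0, bathy[j2, i2] < 200.0}
                    if pair == {True, False}:
                        count += 1
        assert len(sec) == count


class TestSectionFlux:
    def _setup(self):
        ny, nx = 4, 6
        bathy = np.tile(np.linspace(400, 50, nx), (ny, 1))
        grid = make_grid(bathy)
        sec = extract_isobath(grid, 200.0)
        return grid, sec

    def test_zero_velocity_zero_profile(self):
        grid, sec = self._setup()
        state = make_state(grid, u=0.0, v=0.0, nh4=3.0)
        prof = section_flux(state, grid, sec)
        np.testing.assert_allclose(prof.transport_mol_s, 0.0)

    def test_uniform_offshore_flow_closed_form(self):
        grid, sec = self._setup()
        # deep side is at low x; u = -0.1 m/s flows offshore
        state = make_state(grid, u=-0.1, v=0.0, nh4=2.0)
        prof = section_flux(state, grid, sec)
        # faces all normal_sign=-1 -> normal velocity = +0.1 offshore
        total_len = sum(f.length_m for f in sec.faces)
        for kz, (z, dz) in enumerate(zip(prof.z_centers, prof.layer_thickness)):
            wet_len = sum(
                f.length_m for f in sec.faces
                if z < grid.bathymetry[f.j_shallow, f.i_shallow]
            )
            expected = 0.1 * 2.0 * wet_len * dz / 1000.0
            assert prof.transport_mol_s[kz] == pytest.approx(expected)
        assert prof.total_mol_s() > 0
        assert total_len > 0

    def test_brute_force_loop_oracle(self):
        rng_grid = np.random.default_rng(41)
        bathy = rng_grid.uniform(80, 350, size=(5, 7))
        grid = make_grid(bathy)
        sec = extract_isobath(grid, 200.0)
        state = make_state(grid, u=0.05, v=-0.02, nh4=2.0, seed=99)
        prof = section_flux(state, grid, sec)
        # independent loop: per face, per layer, per time
        edges = grid.z_edges()
        thick = np.clip(edges[1:], 0, 200) - np.clip(edges[:-1], 0, 200)
        zsel = [k for k in range(grid.nz) if thick[k] > 0]
        total = np.zeros(len(zsel))
        nt = len(state.time)
        for f in sec.faces:
            vel = state["u"] if f.orientation == "u" else state["v"]
            for kk, k in enumerate(zsel):
                acc = 0.0
                for t in range(nt):
                    va = vel[t, k, f.j_shallow, f.i_shallow]
                    vc = vel[t, k, f.j_deep, f.i_deep]
                    ca = state["NH4"][t, k, f.j_shallow, f.i_shallow]
                    cc = state["NH4"][t, k, f.j_deep, f.i_deep]
                    if np.isnan(va) or np.isnan(ca):
                        continue
                    acc += f.normal_sign * 0.5 * (va + vc) * 0.5 * (ca + cc)
                total[kk] += acc / nt * f.length_m * thick[k]
        np.testing.assert_allclose(prof.transport_mol_s, total / 1000.0, rtol=1e-10)

    def test_velocity_reversal_negates_flux(self):
        grid, sec = self._setup()
        state = make_state(grid, u=0.07, v=-0.03, nh4=1.5, seed=17)
        rev = OceanState(
            time=state.time,
            fields={k: (-np.asarray(v) if k in ("u", "v") else np.asarray(v))
                    for k, v in state.fields.items()},
            scenario_label="rev",
        )
        a = section_flux(state, grid, sec)
        b = section_flux(rev, grid, sec)
        np.testing.assert_allclose(a.transport_mol_s, -b.transport_mol_s, rtol=1e-12)

    def test_face_ordering_invariance(self):
        grid, sec = self._setup()
        state = make_state(grid, u=-0.1, v=0.02, nh4=2.0, seed=55)
        import copy

        shuffled = copy.deepcopy(sec)
        rng = np.random.default_rng(1)
        rng.shuffle(shuffled.faces)
        a = section_flux(state, grid, sec)
        b = section_flux(state, grid, shuffled)
        np.testing.assert_allclose(a.transport_mol_s, b.transport_mol_s, rtol=1e-12)

    def test_missing_velocity_at_wet_face_rejected(self):
        grid, sec = self._setup()
        state = make_state(grid, u=-0.1, v=0.0, nh4=2.0)
        f0 = sec.faces[0]
        bad = state.copy()
        bad.fields["u"][:, 0, f0.j_shallow, f0.i_shallow] = np.nan
        with pytest.raises(IntegrityError, match="missing velocity"):
            section_flux(bad, grid, sec)


class TestFluxChange:
    def test_identity_and_antisymmetry(self):
        ny, nx = 4, 6
        bathy = np.tile(np.linspace(400, 50, nx), (ny, 1))
        grid = make_grid(bathy)
        sec = extract_isobath(grid, 200.0)
        a = section_flux(make_state(grid, u=-0.1, nh4=2.0, seed=1), grid, sec)
        b = section_flux(make_state(grid, u=-0.05, nh4=3.0, seed=2), grid, sec)
        zero = flux_change(a, a)
        np.testing.assert_allclose(zero.transport_mol_s, 0.0)
        ab = flux_change(a, b)
        ba = flux_change(b, a)
        np.testing.assert_allclose(ab.transport_mol_s, -ba.transport_mol_s, rtol=1e-12)

    def test_change_scales_linearly_with_anomaly(self, small_cfg, small_suite):
        """NH4 anomaly scaling propagates linearly into the export change."""
        from eutroscen import synth, transport

        anth, ctrl, grid = synth.make_fixture_pair(small_cfg)
        sec = transport.extract_isobath(grid, 200.0)
        pa = section_flux(anth, grid, sec)
        pc = section_flux(ctrl, grid, sec)
        change = flux_change(pa, pc)
        # a state with anomalies scaled by 0.5 (same background): halve loads
        half = ctrl.copy()
        half.fields["NH4"] = np.asarray(ctrl["NH4"]) + 0.5 * (
            np.asarray(anth["NH4"]) - np.asarray(ctrl["NH4"])
        )
        ph = section_flux(half, grid, sec)
        half_change = flux_change(ph, pc)
        np.testing.assert_allclose(
            half_change.transport_mol_s, 0.5 * change.transport_mol_s,
            rtol=1e-7, atol=1e-9,
        )
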