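"""Meshing and the transient Navier-Stokes solver."""

import numpy as np
import pytest

from carotidrisk import boundary_conditions as bc
from carotidrisk import flow_sim as fs
from carotidrisk import hemo_metrics as hm
from carotidrisk import synth_data as sd


class TestMeshing:
    def test_channel_resolution_across_width(self):
        height = 4e-3
        mesh = fs.straight_channel_mesh(0.01, height, height / 4)
        ys = np.unique(mesh.nodes[:, 1])
        assert len(ys) - 1 >= 4  # at least 4 cells across the channel

    def test_circumdiameter_bound_respected(self):
        geom = sd.generate_geometry(stenosis_severity=0.6, seed=1)
        mesh = fs.mesh_domain(geom, h_max=1.5e-3)
        assert mesh.circumdiameters().max() <= 1.5e-3

    def test_halving_h_at_least_triples_element_count(self):
        geom = sd.generate_geometry(stenosis_severity=0.5, seed=0)
        coarse = fs.mesh_domain(geom, h_max=2.4e-3)
        fine = fs.mesh_domain(geom, h_max=1.2e-3)
        assert len(fine.tris) >= 3 * len(coarse.tris)

    def test_untagged_boundary_edge_rejected(self):
        mesh = fs.straight_channel_mesh(0.01, 4e-3, 1e-3)
        mesh.edge_tags["inlet"] = mesh.edge_tags["inlet"][:-1]  # drop one edge
        with pytest.raises(ValueError, match="untagged"):
            mesh.validate()

    def test_boundary_tags_partition_boundary(self, small_transient):
        small_transient["mesh"].validate()


class TestSteadyBenchmarks:
    def test_poiseuille_centerline_ratio(self, channel):
        space, v = channel["space"], channel["v"]
        mid_x = channel["length"] / 2
        mask = np.isclose(space.coords[:, 0], mid_x, atol=channel["height"] / 8)
        sel = space.coords[mask]
        centerline = v[mask, 0][np.argmin(np.abs(sel[:, 1]))]
        assert centerline / channel["mean_u"] == pytest.approx(1.5, rel=0.02)

    def test_poiseuille_wall_shear_closed_form(self, channel):
        ext = fs._WallShearExtractor(channel["space"])
        tau = ext.tau_w(channel["v"], channel["props"].viscosity)
        expected = 6 * channel["props"].viscosity * channel["mean_u"] / channel["height"]
        assert np.abs(tau).max() == pytest.approx(expected, rel=0.03)
        assert np.abs(tau).min() == pytest.approx(expected, rel=0.03)
        # forward flow drags both walls forward: positive sign convention
        assert np.all(tau > 0)

    def test_poiseuille_pressure_drop(self, channel):
        mesh, p = channel["mesh"], channel["p"]
        inlet_p = p[np.isclose(mesh.nodes[:, 0], 0.0)].mean()
        mu, U, h, L = (channel["props"].viscosity, channel["mean_u"],
                       channel["height"], channel["length"])
        assert inlet_p == pytest.approx(12 * mu * L * U / h**2, rel=0.05)

    def test_outlet_is_zero_pressure_reference(self, channel):
        mesh, p = channel["mesh"], channel["p"]
        outlet_p = p[np.isclose(mesh.nodes[:, 0], channel["length"])].mean()
        inlet_p = p[np.isclose(mesh.nodes[:, 0], 0.0)].mean()
        assert abs(outlet_p) <= 0.02 * abs(inlet_p)

    def test_wss_error_decreases_under_refinement(self):
        props = bc.FluidProps()
        U, h = 0.2, 4e-3
        expected = 6 * props.viscosity * U / h
        errs = []
        for hmax in [2.0e-3, 1.0e-3, 0.5e-3]:
            length = 0.012
            mesh = fs.straight_channel_mesh(length, h, hmax)
            v, _, space = fs.solve_steady(
                mesh, fs.DirichletBC("inlet", props.density * U * h), props=props
            )
            ext = fs._WallShearExtractor(space)
            tau = np.abs(ext.tau_w(v, props.viscosity))
            # measure away from the inlet and the do-nothing outlet corner
            # (the corner carries a local boundary-condition artifact that
            # sharpens rather than decays under refinement)
            per = ext.arclengths % length
            inner = (per > 0.25 * length) & (per < 0.75 * length)
            errs.append(np.abs(tau[inner] - expected).max() / expected)
        assert errs[0] > errs[1] > errs[2]

    def test_stokes_regime_reversal_flips_wall_shear(self):
        props = bc.FluidProps()
        mesh = fs.straight_channel_mesh(0.01, 4e-3, 1e-3)
        mdot = props.density * 1e-5 * 4e-3  # creeping flow, Re ~ 0.01
        vp, _, space = fs.solve_steady(mesh, fs.DirichletBC("inlet", mdot),
                                       props=props, tol=1e-10)
        vm, _, _ = fs.solve_steady(mesh, fs.DirichletBC("inlet", -mdot),
                                   props=props, tol=1e-10)
        ext = fs._WallShearExtractor(space)
        tp = ext.tau_w(vp, props.viscosity)
        tm = ext.tau_w(vm, props.viscosity)
        # the residual asymmetry is the O(Re) convective nonlinearity
        assert np.abs(tp + tm).max() <= 1e-3 * np.abs(tp).max()


class TestTransient:
    def test_zero_inflow_gives_zero_fields(self):
        geom = sd.generate_geometry(stenosis_severity=0.3, seed=0)
        mesh = fs.mesh_domain(geom, h_max=2.5e-3)
        sol = fs.solve_transient(
            mesh,
            fs.DirichletBC("inlet", 0.0),
            fs.DirichletBC("outlet_eca", 0.0, outflow=True),
            bc.FluidProps(),
            dt=0.1,
            n_cycles=1,
            period=0.5,
        )
        assert np.abs(sol.U).max() == pytest.approx(0.0, abs=1e-12)
        assert np.abs(sol.P).max() == pytest.approx(0.0, abs=1e-8)
        rec = fs.wall_shear_series(sol)
        assert np.abs(rec.tau).max() == pytest.approx(0.0, abs=1e-12)

    def test_mass_conservation_every_stored_step(self, small_transient):
        sol = small_transient["sol"]
        space = fs.make_space(small_transient["mesh"])
        for k in range(1, len(sol.times)):
            fin = fs.boundary_flux(space, sol.U[k], "inlet")
            f_ica = fs.boundary_flux(space, sol.U[k], "outlet_ica")
            f_eca = fs.boundary_flux(space, sol.U[k], "outlet_eca")
            assert abs(fin + f_ica + f_eca) <= 0.01 * abs(fin)

    def test_weak_incompressibility_residual(self, small_transient):
        assert small_transient["sol"].div_residual <= 1e-6

    def test_cycle_to_cycle_tawss_periodicity(self, small_transient):
        sol = small_transient["sol"]
        tw_prev = hm.tawss(sol.wall_records[-2])
        tw_last = hm.tawss(sol.wall_records[-1])
        assert np.abs(tw_last - tw_prev).max() <= 0.02 * tw_last.max()

    def test_ica_outlet_stays_near_zero_pressure(self, small_transient):
        traces = fs.boundary_pressure_series(small_transient["sol"])
        scale = max(np.abs(traces["inlet"]).max(), 1e-12)
        assert np.abs(traces["outlet_ica"]).max() <= 0.05 * scale

    def test_wall_shear_record_well_formed(self, small_transient):
        rec = fs.wall_shear_series(small_transient["sol"])
        rec.validate()
        assert rec.tau.shape == (len(rec.arclengths), len(rec.times))
        assert np.all(np.diff(rec.arclengths) > 0)

    def test_solution_validates(self, small_transient):
        small_transient["sol"].validate()


class TestExport:
    def test_vtk_writer_roundtrip_header(self, tmp_path, channel):
        path = tmp_path / "field.vtk"
        mesh = channel["mesh"]
        fs.write_vtk(path, mesh,
                     point_data={"p": channel["p"],
                                 "v": channel["v"][: len(mesh.nodes)]})
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk")
        assert f"POINTS {len(mesh.nodes)} double" in text
        assert f"CELL_TYPES {len(mesh.tris)}" in text
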