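"""Mooney-Rivlin constitutive law and the plane-strain structural solver."""

import numpy as np
import pytest

from carotidrisk import plaque_stress as ps
from carotidrisk import synth_data as sd


def _ring_geom(arc_deg=120.0):
    return sd.CrossSectionGeometry(
        r_lumen=2.5e-3, r_outer=4.0e-3, r_plaque_inner=2.8e-3,
        r_plaque_outer=3.4e-3, arc_centre=0.3, arc_extent=np.deg2rad(arc_deg),
    )


def _random_plane_strain_F(rng, scale=0.15):
    F = np.eye(3)
    F[:2, :2] += scale * rng.standard_normal((2, 2))
    if np.linalg.det(F) <= 0.05:
        F = np.eye(3)
    return F


class TestConstitutive:
    def test_reference_state_is_stress_free(self):
        for mat in (ps.WALL_MATERIAL, ps.FIBROSIS_MATERIAL):
            assert np.abs(ps.mooney_rivlin_stress(mat, np.eye(3))).max() == 0.0
            assert ps.strain_energy(mat, np.eye(3)) == pytest.approx(0.0, abs=1e-20)

    def test_incompressible_uniaxial_neo_hookean_closed_form(self):
        """At J=1 the stress difference sigma_axial - sigma_lateral equals
        2 C10 (lambda^2 - 1/lambda) (the hydrostatic part drops out)."""
        mat = ps.MaterialMR({(1, 0): 0.07e6}, 1e-5)
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        sig = ps.mooney_rivlin_stress(mat, F)
        expected = 2 * 0.07e6 * (lam**2 - 1 / lam)
        assert sig[0, 0] - sig[1, 1] == pytest.approx(expected, rel=1e-8)

    def test_stress_tensor_symmetric_for_random_gradients(self):
        rng = np.random.default_rng(0)
        F = np.stack([_random_plane_strain_F(rng) for _ in range(1000)])
        sig = ps.mooney_rivlin_stress(ps.WALL_MATERIAL, F)
        assert np.allclose(sig, np.swapaxes(sig, -1, -2), atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_analytic_stress_matches_energy_derivative(self, seed):
        """sigma from S = 2 dW/dC agrees with a central finite difference of
        W through P = dW/dF, sigma = P F^T / J, to 1e-6 relative."""
        rng = np.random.default_rng(seed)
        coeffs = {
            (1, 0): rng.uniform(0.01e6, 0.2e6),
            (0, 1): rng.uniform(0.0, 0.1e6),
            (2, 0): rng.uniform(0.0, 2e6),
            (1, 1): rng.uniform(-0.5e6, 0.5e6),
            (2, 1): rng.uniform(0.0, 0.1e6),
        }
        mat = ps.MaterialMR(coeffs, 1e-5)
        F = _random_plane_strain_F(rng, scale=0.1)
        sig = ps.mooney_rivlin_stress(mat, F)
        h = 1e-7
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                dF = np.zeros((3, 3))
                dF[i, j] = h
                P[i, j] = (
                    ps.strain_energy(mat, F + dF) - ps.strain_energy(mat, F - dF)
                ) / (2 * h)
        sig_fd = P @ F.T / np.linalg.det(F)
        assert np.abs(sig - sig_fd).max() <= 1e-6 * max(np.abs(sig).max(), 1.0)

    def test_objectivity_under_superposed_rotation(self):
        rng = np.random.default_rng(2)
        F = _random_plane_strain_F(rng)
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        s1 = np.sort(np.linalg.eigvalsh(ps.mooney_rivlin_stress(ps.WALL_MATERIAL, F)))
        s2 = np.sort(np.linalg.eigvalsh(ps.mooney_rivlin_stress(ps.WALL_MATERIAL, R @ F)))
        assert np.allclose(s1, s2, rtol=1e-10, atol=1e-4)

    def test_inverted_gradient_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            ps.mooney_rivlin_stress(ps.WALL_MATERIAL, -np.eye(3))

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            ps.MaterialMR({(4, 0): 1.0}, 1e-5)


class TestMeshing:
    def test_homogeneous_ring_all_wall(self):
        geom = sd.CrossSectionGeometry(
            r_lumen=2.5e-3, r_outer=4.0e-3, r_plaque_inner=2.8e-3,
            r_plaque_outer=3.4e-3, arc_centre=0.0, arc_extent=0.0,
        )
        mesh = ps.mesh_cross_section(geom, face_size=0.5e-3)
        assert np.all(mesh.regions == 0)

    def test_plaque_wall_interface_nodes_shared(self):
        mesh = ps.mesh_cross_section(_ring_geom(), face_size=0.5e-3)
        plaque_nodes = set(mesh.tris[mesh.regions == 1].ravel())
        wall_nodes = set(mesh.tris[mesh.regions == 0].ravel())
        assert len(plaque_nodes & wall_nodes) >= 8  # bonded interface

    def test_halving_face_size_at_least_triples_elements(self):
        # at the default (50 micron) scale the base grid dominates the
        # constant-count inflation layers, so halving the size almost
        # quadruples the count
        coarse = ps.mesh_cross_section(_ring_geom(), face_size=0.05e-3)
        fine = ps.mesh_cross_section(_ring_geom(), face_size=0.025e-3)
        assert len(fine.tris) >= 3 * len(coarse.tris)

    def test_plaque_area_fraction_matches_analytic(self):
        geom = _ring_geom()
        mesh = ps.mesh_cross_section(geom, face_size=0.3e-3)
        p = mesh.nodes[mesh.tris]
        u, w = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
        areas = 0.5 * np.abs(u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0])
        frac = areas[mesh.regions == 1].sum() / areas.sum()
        assert frac == pytest.approx(geom.plaque_area_fraction(), rel=0.03)


@pytest.fixture(scope="module")
def ring_mesh():
    return ps.mesh_cross_section(_ring_geom(), face_size=0.5e-3)


class TestSolver:
    def test_zero_pressure_gives_zero_state(self, ring_mesh):
        sol = ps.solve_structural(
            ring_mesh, {"wall": ps.WALL_MATERIAL, "plaque": ps.FIBROSIS_MATERIAL}, 0.0
        )
        assert sol.max_deformation == 0.0
        assert np.abs(sol.element_stress).max() == 0.0
        info = ps.plaque_structural_stress(sol)
        assert info["pss"] == 0.0 and info["max_deformation"] == 0.0

    def test_pressurized_ring_matches_lame_hoop_stress(self, ring_mesh):
        """Free outer boundary, homogeneous material, small load: hoop
        stress tracks the thick-walled-cylinder solution (plane-strain
        stresses are independent of Poisson ratio)."""
        mat = ps.MaterialMR({(1, 0): 0.07e6}, 1e-5)
        p = 1e3
        sol = ps.solve_structural(
            ring_mesh, {"wall": mat, "plaque": mat}, p, outer_bc="free"
        )
        a, b = 2.5e-3, 4.0e-3
        cent = ring_mesh.nodes[ring_mesh.tris].mean(axis=1)
        r = np.linalg.norm(cent, axis=1)
        lame = p * a**2 / (b**2 - a**2) * (1 + b**2 / r**2)
        princ = sol.principal_stress()
        rel = np.abs(princ - lame) / lame
        assert np.median(rel) <= 0.05

    def test_linear_regime_doubling_pressure_doubles_deformation(self, ring_mesh):
        mats = {"wall": ps.WALL_MATERIAL, "plaque": ps.FIBROSIS_MATERIAL}
        d1 = ps.solve_structural(ring_mesh, mats, 500.0).max_deformation
        d2 = ps.solve_structural(ring_mesh, mats, 1000.0).max_deformation
        assert d2 / d1 == pytest.approx(2.0, rel=0.02)

    def test_uniform_pressure_axisymmetric_on_homogeneous_ring(self):
        geom = sd.CrossSectionGeometry(
            r_lumen=2.5e-3, r_outer=4.0e-3, r_plaque_inner=2.8e-3,
            r_plaque_outer=3.4e-3, arc_centre=0.0, arc_extent=0.0,
        )
        mesh = ps.mesh_cross_section(geom, face_size=0.5e-3)
        mat = ps.MaterialMR({(1, 0): 0.07e6}, 1e-5)
        sol = ps.solve_structural(mesh, {"wall": mat}, 1e3, outer_bc="free")
        # compare elements within one radial layer across angles
        cent = mesh.nodes[mesh.tris].mean(axis=1)
        r = np.linalg.norm(cent, axis=1)
        princ = sol.principal_stress()
        layers = np.unique(np.round(r, 9))
        mid_layer = layers[len(layers) // 2]
        sel = np.isclose(r, mid_layer)
        spread = np.ptp(princ[sel]) / np.abs(princ[sel]).mean()
        assert spread <= 0.01

    def test_pss_monotone_in_pressure(self, ring_mesh):
        mats = {"wall": ps.WALL_MATERIAL, "plaque": ps.FIBROSIS_MATERIAL}
        values = [
            ps.plaque_structural_stress(ps.solve_structural(ring_mesh, mats, p))["pss"]
            for p in [2e3, 4e3, 7e3, 10e3, 13e3]
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_thin_cap_raises_pss(self):
        mats = {"wall": ps.WALL_MATERIAL, "plaque": ps.FIBROSIS_MATERIAL}
        thin = sd.generate_cross_section(cap_thickness=0.15e-3, seed=0,
                                         plaque_thickness=0.7e-3)
        thick = sd.generate_cross_section(cap_thickness=0.45e-3, seed=0,
                                          plaque_thickness=0.7e-3)
        pss = {}
        for name, geom in [("thin", thin), ("thick", thick)]:
            mesh = ps.mesh_cross_section(geom, face_size=0.4e-3)
            sol = ps.solve_structural(mesh, mats, 10e3)
            pss[name] = ps.plaque_structural_stress(sol)["pss"]
        assert pss["thin"] > pss["thick"]

    def test_missing_material_rejected(self, ring_mesh):
        with pytest.raises(ValueError, match="material"):
            ps.solve_structural(ring_mesh, {"wall": ps.WALL_MATERIAL}, 1e3)

    def test_outer_normal_displacement_constrained(self, ring_mesh):
        sol = ps.solve_structural(
            ring_mesh, {"wall": ps.WALL_MATERIAL, "plaque": ps.FIBROSIS_MATERIAL}, 5e3
        )
        outer = set()
        for a, b in ring_mesh.edge_tags["outer"]:
            outer.update((int(a), int(b)))
        ids = np.array(sorted(outer))
        x = sol.coords[ids]
        n = x / np.linalg.norm(x, axis=1, keepdims=True)
        un = np.abs(np.einsum("ij,ij->i", sol.displacements[ids], n))
        assert un.max() <= 1e-12 * max(sol.max_deformation, 1e-30) + 1e-16
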