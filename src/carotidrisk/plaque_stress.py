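"""Plane-strain hyperelastic analysis of a plaque-bearing cross-section.

The cross-section with the largest plaque burden is loaded on its luminal
boundary with the cycle-maximum site pressure from the flow simulation.  The
arterial wall and the fibrous plaque are polynomial Mooney-Rivlin solids,

    W = sum_{i+j<=3} C_ij (I1b - 3)^i (I2b - 3)^j + (1/d) (J - 1)^2,

with isochoric invariants I1b = J^(-2/3) I1, I2b = J^(-4/3) I2 and the
volumetric penalty 1/d.  Supported coefficients go up to third order so the
published wall constants (C10, C20 and the third-order C21) are representable
verbatim.

Discretization: quadratic displacement triangles on a polar block mesh with
conforming (bonded-by-construction) plaque/wall interfaces and two half-size
element layers along the lumen and plaque interfaces standing in for the
boundary-layer inflation.  Boundary conditions: frictionless support on the
outer perimeter (zero normal displacement, free tangential slip) and a
follower pressure load on the lumen.  The nonlinear system is solved by
Newton iteration on the total-Lagrangian weak form with incremental loading
and automatic step halving.

Outputs: displacement and Cauchy-stress fields, the plaque structural
stress PSS (maximum first principal Cauchy stress over the plaque and the
fibrous-cap strip) and the maximum deformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import (
    GAUSS3_1D,
    TriMesh,
    build_p2,
    element_geometry,
    p2_basis,
    p2_edge_basis,
    quad_rule,
)
from .synth_data import CrossSectionGeometry

logger = logging.getLogger(__name__)

Mesh = TriMesh

_MID_REF = {3: (0.5, 0.0), 4: (0.5, 0.5), 5: (0.0, 0.5)}


# ---------------------------------------------------------------------------
# constitutive model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialMR:
    """Polynomial Mooney-Rivlin material (orders i+j <= 3).

    ``coeffs`` maps (i, j) -> C_ij in Pa; ``d`` is the incompressibility
    parameter in 1/Pa (volumetric stiffness 2/d).
    """

    coeffs: dict[tuple[int, int], float]
    d: float

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("incompressibility parameter d must be positive")
        for (i, j) in self.coeffs:
            if i < 0 or j < 0 or i + j < 1 or i + j > 3:
                raise ValueError(f"unsupported Mooney-Rivlin order ({i},{j})")
        mu0 = 2 * (self.coeffs.get((1, 0), 0.0) + self.coeffs.get((0, 1), 0.0))
        if mu0 < 0:
            raise ValueError("initial shear modulus 2(C10 + C01) must be >= 0")

    @property
    def initial_shear_modulus(self) -> float:
        return 2 * (self.coeffs.get((1, 0), 0.0) + self.coeffs.get((0, 1), 0.0))


#: Arterial-wall constants (C10 = 0.07 MPa, C20 = 3.2 MPa, C21 = 0.0716 MPa,
#: remaining orders zero; d = 1e-5 1/Pa).
WALL_MATERIAL = MaterialMR({(1, 0): 0.07e6, (2, 0): 3.2e6, (2, 1): 0.0716e6}, 1e-5)

#: Fibrotic-plaque 5-parameter constants.
FIBROSIS_MATERIAL = MaterialMR(
    {
        (1, 0): -3.3232e6,
        (0, 1): 3.4296e6,
        (2, 0): 4.5387e8,
        (1, 1): -1.021e9,
        (0, 2): 5.8132e8,
    },
    1e-5,
)


def strain_energy(mat: MaterialMR, F: np.ndarray) -> np.ndarray:
    """Strain-energy density W(F) for deformation gradients (..., 3, 3)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    C2 = np.einsum("...ik,...kj->...ij", C, C)
    I2 = 0.5 * (I1**2 - np.trace(C2, axis1=-2, axis2=-1))
    a = J ** (-2.0 / 3.0) * I1 - 3.0
    b = J ** (-4.0 / 3.0) * I2 - 3.0
    W = (1.0 / mat.d) * (J - 1.0) ** 2
    for (i, j), cij in mat.coeffs.items():
        W = W + cij * a**i * b**j
    return W


def mooney_rivlin_stress(mat: MaterialMR, deformation_gradient: np.ndarray) -> np.ndarray:
    """Cauchy stress sigma(F) for deformation gradients (..., 3, 3).

    Derived analytically from S = 2 dW/dC with the isochoric-volumetric
    split; sigma = J^-1 F S F^T.
    """
    F = np.asarray(deformation_gradient, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = np.linalg.inv(C)
    eye = np.broadcast_to(np.eye(3), C.shape)
    I1 = np.trace(C, axis1=-2, axis2=-1)[..., None, None]
    C2 = np.einsum("...ik,...kj->...ij", C, C)
    I2 = 0.5 * (I1[..., 0, 0] ** 2 - np.trace(C2, axis1=-2, axis2=-1))[..., None, None]
    Jn = J[..., None, None]
    a = (Jn[..., 0, 0] ** (-2.0 / 3.0) * I1[..., 0, 0] - 3.0)[..., None, None]
    b = (Jn[..., 0, 0] ** (-4.0 / 3.0) * I2[..., 0, 0] - 3.0)[..., None, None]

    dI1b = Jn ** (-2.0 / 3.0) * (eye - (I1 / 3.0) * Cinv)
    dI2b = Jn ** (-4.0 / 3.0) * (I1 * eye - C - (2.0 * I2 / 3.0) * Cinv)

    dWdC = np.zeros_like(C)
    for (i, j), cij in mat.coeffs.items():
        if i > 0:
            dWdC = dWdC + cij * i * _safe_pow(a, i - 1) * _safe_pow(b, j) * dI1b
        if j > 0:
            dWdC = dWdC + cij * j * _safe_pow(a, i) * _safe_pow(b, j - 1) * dI2b
    # volumetric: d/dC (1/d)(J-1)^2 = (2/d)(J-1) * (J/2) C^-1
    dWdC = dWdC + (1.0 / mat.d) * (Jn - 1.0) * Jn * Cinv
    S = 2.0 * dWdC
    sigma = np.einsum("...ik,...kl,...jl->...ij", F, S, F) / Jn
    return sigma


def _safe_pow(x: np.ndarray, n: int) -> np.ndarray:
    return np.ones_like(x) if n == 0 else x**n


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def _graded_segment(r0: float, r1: float, size: float) -> np.ndarray:
    """Radii from r0 to r1, spacing <= size, with the first and last cells
    split in half twice (two half-size 'inflation' layers per interface)."""
    n = max(2, int(np.ceil((r1 - r0) / size)))
    r = np.linspace(r0, r1, n + 1)
    first = r0 + (r[1] - r0) * np.array([0.25, 0.5])
    last = r[-2] + (r1 - r[-2]) * np.array([0.5, 0.75])
    return np.unique(np.concatenate([r, first, last]))


def mesh_cross_section(geom: CrossSectionGeometry, face_size: float = 0.05e-3) -> Mesh:
    """Region-tagged polar block mesh of the annular cross-section.

    Plaque and wall share interface nodes (bonded contact by construction);
    the radial grid carries half-size layers at the lumen and plaque
    interfaces.  Boundary tags: 'lumen' (inner circle) and 'outer'.
    """
    if face_size <= 0:
        raise ValueError("face_size must be positive")
    geom.validate()
    rl, rp0, rp1, ro = (
        geom.r_lumen,
        geom.r_plaque_inner,
        geom.r_plaque_outer,
        geom.r_outer,
    )
    radii = np.unique(
        np.concatenate(
            [
                _graded_segment(rl, rp0, face_size),
                _graded_segment(rp0, rp1, face_size),
                _graded_segment(rp1, ro, face_size),
            ]
        )
    )
    th0 = geom.arc_centre - geom.arc_extent / 2
    th1 = geom.arc_centre + geom.arc_extent / 2
    dth = face_size / ro
    if geom.arc_extent > 0.0:
        n_in = max(3, int(np.ceil((th1 - th0) / dth)))
        n_out = max(3, int(np.ceil((2 * np.pi - (th1 - th0)) / dth)))
        thetas = np.concatenate(
            [np.linspace(th0, th1, n_in + 1),
             np.linspace(th1, th0 + 2 * np.pi, n_out + 1)[1:-1]]
        )
    else:  # homogeneous ring: uniform circle grid
        n_out = max(8, int(np.ceil(2 * np.pi / dth)))
        thetas = np.linspace(th0, th0 + 2 * np.pi, n_out + 1)[:-1]
    nth = len(thetas)

    nr = len(radii)
    nodes = np.empty((nr * nth, 2))
    for i, r in enumerate(radii):
        nodes[i * nth : (i + 1) * nth, 0] = r * np.cos(thetas)
        nodes[i * nth : (i + 1) * nth, 1] = r * np.sin(thetas)

    idx = lambda i, j: i * nth + (j % nth)
    tris = []
    regions = []
    r_mid = 0.5 * (radii[:-1] + radii[1:])
    has_plaque = geom.arc_extent > 0.0
    for i in range(nr - 1):
        in_band = has_plaque and (rp0 - 1e-12 <= r_mid[i] <= rp1 + 1e-12)
        for j in range(nth):
            th_a, th_b = thetas[j], thetas[(j + 1) % nth]
            if j == nth - 1:
                th_b = th0 + 2 * np.pi
            th_mid = 0.5 * (th_a + th_b)
            in_sector = th0 - 1e-12 <= th_mid <= th1 + 1e-12
            reg = 1 if (in_band and in_sector) else 0
            tris.append((idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)))
            regions.append(reg)
            tris.append((idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)))
            regions.append(reg)

    lumen_edges = [(idx(0, j), idx(0, j + 1)) for j in range(nth)]
    outer_edges = [(idx(nr - 1, j + 1), idx(nr - 1, j)) for j in range(nth)]
    mesh = Mesh(
        nodes=nodes,
        tris=np.array(tris),
        edge_tags={"lumen": np.array(lumen_edges), "outer": np.array(outer_edges)},
        regions=np.array(regions),
        region_names={0: "wall", 1: "plaque"},
        metadata={
            "kind": "cross_section",
            "r_lumen": rl,
            "r_plaque_inner": rp0,
            "r_plaque_outer": rp1,
            "r_outer": ro,
            "arc_centre": geom.arc_centre,
            "arc_extent": geom.arc_extent,
        },
    )
    mesh.h = float(mesh.circumdiameters().max())
    try:
        mesh.validate()
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"cross-section meshing failed: {exc}") from exc
    if has_plaque and not np.any(mesh.regions == 1):
        raise RuntimeError("cross-section meshing failed: empty plaque region")
    return mesh


# ---------------------------------------------------------------------------
# structural solver
# ---------------------------------------------------------------------------


@dataclass
class StructuralSolution:
    """Converged displacement and stress state of one cross-section."""

    mesh: Mesh
    coords: np.ndarray  # P2 node coordinates
    displacements: np.ndarray  # (n2, 2)
    element_stress: np.ndarray  # (ne, 3, 3) Cauchy stress at element centroid
    pressure: float
    residual: float
    max_deformation: float = field(init=False)

    def __post_init__(self):
        self.max_deformation = float(
            np.linalg.norm(self.displacements, axis=1).max()
        )

    def principal_stress(self) -> np.ndarray:
        """First (largest) principal Cauchy stress per element."""
        return np.linalg.eigvalsh(self.element_stress)[:, -1]

    def von_mises(self) -> np.ndarray:
        s = self.element_stress
        dev = s - np.trace(s, axis1=1, axis2=2)[:, None, None] / 3.0 * np.eye(3)
        return np.sqrt(1.5 * np.einsum("eij,eij->e", dev, dev))


def _outer_constraints(mesh: Mesh, coords: np.ndarray, edge_mid: dict,
                       mode: str) -> sp.csr_matrix:
    """Reduction matrix T (2*n2 x n_free) encoding the outer-boundary BC.

    'support': frictionless support — outer nodes keep only their tangential
    dof.  'free': traction-free outer boundary with three point constraints
    pinning the rigid modes (consistent with axisymmetric states).
    """
    n2 = len(coords)
    outer_nodes = set()
    for a, b in mesh.edge_tags["outer"]:
        outer_nodes.add(int(a))
        outer_nodes.add(int(b))
        outer_nodes.add(edge_mid[tuple(sorted((int(a), int(b))))])

    rows, cols, vals = [], [], []
    col = 0
    if mode == "support":
        # the tangential dof of one outer node is removed as well: with
        # u.n = 0 everywhere on the outer ring, a rigid rotation about the
        # centre is an (infinitesimal) zero-energy mode that would make the
        # tangent matrix singular
        anchor = min(outer_nodes)
        for node in range(n2):
            if node == anchor:
                col += 0
            elif node in outer_nodes:
                x, y = coords[node]
                r = np.hypot(x, y)
                t = np.array([-y / r, x / r])
                rows += [2 * node, 2 * node + 1]
                cols += [col, col]
                vals += [t[0], t[1]]
                col += 1
            else:
                rows += [2 * node, 2 * node + 1]
                cols += [col, col + 1]
                vals += [1.0, 1.0]
                col += 2
    elif mode == "free":
        outer = np.array(sorted(outer_nodes))
        ang = np.arctan2(coords[outer, 1], coords[outer, 0])
        # pin u_y on the +x and -x axis nodes and u_x on the +y axis node:
        # removes the three rigid modes without constraining axisymmetric states
        pin_y = {int(outer[np.argmin(np.abs(ang))]),
                 int(outer[np.argmin(np.abs(np.abs(ang) - np.pi))])}
        pin_x = {int(outer[np.argmin(np.abs(ang - np.pi / 2))])}
        for node in range(n2):
            drop = set()
            if node in pin_y:
                drop.add(1)
            if node in pin_x:
                drop.add(0)
            for comp in (0, 1):
                if comp in drop:
                    continue
                rows.append(2 * node + comp)
                cols.append(col)
                vals.append(1.0)
                col += 1
    else:
        raise ValueError(f"unknown outer boundary mode {mode!r}")
    return sp.csr_matrix((vals, (rows, cols)), shape=(2 * n2, col))


class _StructuralSystem:
    def __init__(self, mesh: Mesh, materials: dict[str, MaterialMR]):
        self.mesh = mesh
        self.coords, self.elems, self.edge_mid = build_p2(mesh)
        self.invJT, self.detJ = element_geometry(mesh)
        qp, qw = quad_rule(4)
        _, dN = p2_basis(qp)
        self.qw = qw
        self.grads = np.einsum("eij,qbj->qebi", self.invJT, dN)  # (nq, ne, 6, 2)
        self.n2 = len(self.coords)
        names = mesh.region_names or {0: "wall"}
        regions = mesh.regions if mesh.regions is not None else np.zeros(len(mesh.tris), int)
        for rid in np.unique(regions):
            if names[int(rid)] not in materials:
                raise ValueError(f"no material supplied for region {names[int(rid)]!r}")
        self.mat_of_elem = [materials[names[int(r)]] for r in regions]
        # group elements by material for vectorized stress evaluation
        self.groups: list[tuple[MaterialMR, np.ndarray]] = []
        for mat in {id(m): m for m in self.mat_of_elem}.values():
            ids = np.array([i for i, m in enumerate(self.mat_of_elem) if m is mat])
            self.groups.append((mat, ids))
        # lumen boundary data for the follower load
        self.lumen = []
        for a, b in mesh.edge_tags["lumen"]:
            a, b = int(a), int(b)
            mid = self.edge_mid[tuple(sorted((a, b)))]
            self.lumen.append((a, b, mid))
        self.lumen = np.array(self.lumen)

    # -- kinematics ---------------------------------------------------------
    def _def_gradients(self, u: np.ndarray) -> np.ndarray:
        """F (nq, ne, 3, 3) with F33 = 1 (plane strain)."""
        u_el = u[self.elems]  # (ne, 6, 2)
        gradu = np.einsum("ebi,qebj->qeij", u_el, self.grads)  # (nq, ne, 2, 2)
        nq, ne = gradu.shape[:2]
        F = np.zeros((nq, ne, 3, 3))
        F[..., :2, :2] = gradu + np.eye(2)
        F[..., 2, 2] = 1.0
        return F

    def _pk1(self, F: np.ndarray) -> np.ndarray:
        """In-plane first Piola-Kirchhoff stress (nq, ne, 2, 2)."""
        P = np.empty(F.shape[:2] + (2, 2))
        for mat, ids in self.groups:
            Fg = F[:, ids]
            J = np.linalg.det(Fg)
            sigma = mooney_rivlin_stress(mat, Fg)
            # P = J sigma F^-T, restricted to in-plane components
            FinvT = np.linalg.inv(Fg).swapaxes(-1, -2)
            Pg = J[..., None, None] * np.einsum("...ik,...kj->...ij", sigma, FinvT)
            P[:, ids] = Pg[..., :2, :2]
        return P

    # -- assembly -----------------------------------------------------------
    def internal_force(self, u: np.ndarray) -> np.ndarray:
        F = self._def_gradients(u)
        P = self._pk1(F)
        w = self.qw[:, None] * self.detJ[None, :]
        fl = np.einsum("qe,qebj,qeij->ebi", w, self.grads, P)  # (ne, 6, 2)
        f = np.zeros((self.n2, 2))
        np.add.at(f, self.elems, fl)
        return f.ravel()

    def tangent(self, u: np.ndarray) -> sp.csr_matrix:
        F = self._def_gradients(u)
        nq, ne = F.shape[:2]
        A = np.empty((nq, ne, 2, 2, 2, 2))
        eps_fd = 1e-7
        for k in range(2):
            for l in range(2):
                dF = np.zeros((3, 3))
                dF[k, l] = eps_fd
                Pp = self._pk1(F + dF)
                Pm = self._pk1(F - dF)
                A[..., k, l] = (Pp - Pm) / (2 * eps_fd)
        w = self.qw[:, None] * self.detJ[None, :]
        # K[e, a i, b k] = sum_q w grad[a,j] A[i,j,k,l] grad[b,l]
        Kl = np.einsum("qe,qebj,qeijkl,qecl->ebick", w, self.grads,
                       A.transpose(0, 1, 3, 2, 4, 5), self.grads)
        # rows/cols over (node, comp) dofs
        dof = (2 * self.elems[:, :, None] + np.arange(2)[None, None, :]).reshape(ne, 12)
        rows = np.repeat(dof[:, :, None], 12, axis=2)
        cols = np.repeat(dof[:, None, :], 12, axis=1)
        Kflat = Kl.reshape(ne, 12, 12)
        return sp.coo_matrix(
            (Kflat.ravel(), (rows.ravel(), cols.ravel())),
            shape=(2 * self.n2, 2 * self.n2),
        ).tocsr()

    def external_force(self, u: np.ndarray, pressure: float) -> np.ndarray:
        """Follower pressure on the (deformed) lumen boundary."""
        f = np.zeros((self.n2, 2))
        if pressure == 0.0 or len(self.lumen) == 0:
            return f.ravel()
        xi, wq = GAUSS3_1D
        N, dN = p2_edge_basis(xi)
        x = self.coords + u
        for a, b, mid in self.lumen:
            ids = np.array([a, b, mid])
            xe = x[ids]  # (3, 2)
            tq = dN @ xe  # (3q, 2) dx/dxi
            mids = N @ xe
            # normal toward the centre = outward normal of the solid on the
            # inner boundary; traction = -p * n_solid = +p * radial
            nq_ = np.stack([tq[:, 1], -tq[:, 0]], axis=1)
            sgn = np.sign(np.einsum("qi,qi->q", nq_, mids))
            nq_ = nq_ * sgn[:, None]  # now points away from the centre
            trac = pressure * nq_  # (3q, 2), includes |dx/dxi| via nq_ norm
            fl = np.einsum("q,qa,qi->ai", wq, N, trac)
            np.add.at(f, ids, fl)
        return f.ravel()


def solve_structural(
    mesh: Mesh,
    materials: dict[str, MaterialMR],
    luminal_pressure: float,
    outer_bc: str = "support",
    n_increments: int = 4,
    newton_tol: float = 1e-6,
    max_newton: int = 30,
) -> StructuralSolution:
    """Incremental Newton solve of the pressurised cross-section.

    The load is applied in ``n_increments`` steps with automatic halving on
    divergence; each step iterates until the reduced residual falls below
    ``newton_tol`` relative to the external load.
    """
    if luminal_pressure < 0:
        raise ValueError("pressure must be >= 0")
    sys = _StructuralSystem(mesh, materials)
    T = _outer_constraints(mesh, sys.coords, sys.edge_mid, outer_bc)
    u = np.zeros((sys.n2, 2))
    if luminal_pressure == 0.0:
        return _finalize(sys, mesh, u, 0.0, 0.0)

    p_done = 0.0
    dp = luminal_pressure / n_increments
    halvings = 0
    res_norm = 0.0
    while p_done < luminal_pressure - 1e-12 * luminal_pressure:
        p_target = min(luminal_pressure, p_done + dp)
        u_trial = u.copy()
        ok = False
        fext_ref = None
        for _ in range(max_newton):
            fext = sys.external_force(u_trial, p_target)
            R = sys.internal_force(u_trial) - fext
            Rr = T.T @ R
            if fext_ref is None:
                fext_ref = max(np.linalg.norm(T.T @ fext), 1e-30)
            res_norm = np.linalg.norm(Rr) / fext_ref
            if res_norm < newton_tol:
                ok = True
                break
            K = sys.tangent(u_trial)
            Kr = (T.T @ K @ T).tocsc()
            try:
                da = spla.spsolve(Kr, -Rr)
            except Exception:
                break
            if not np.isfinite(da).all():
                break
            u_trial = u_trial + (T @ da).reshape(-1, 2)
            # guard against inverted elements
            F = sys._def_gradients(u_trial)
            if np.any(np.linalg.det(F) <= 0):
                break
        if ok:
            u = u_trial
            p_done = p_target
        else:
            dp *= 0.5
            halvings += 1
            if halvings > 8:
                raise RuntimeError(
                    f"structural solve failed to converge (last residual {res_norm:.3g})"
                )
    return _finalize(sys, mesh, u, luminal_pressure, res_norm)


def _finalize(sys: _StructuralSystem, mesh, u, pressure, residual) -> StructuralSolution:
    Fq = sys._def_gradients(u)
    stress = np.zeros((Fq.shape[1], 3, 3))
    wsum = sys.qw.sum()
    for mat, ids in sys.groups:
        sg = mooney_rivlin_stress(mat, Fq[:, ids])  # (nq, nels, 3, 3)
        stress[ids] = np.einsum("q,qeij->eij", sys.qw, sg) / wsum
    return StructuralSolution(mesh, sys.coords, u, stress, pressure, residual)


def plaque_structural_stress(sol: StructuralSolution) -> dict:
    """PSS = max first principal Cauchy stress over the plaque and the
    fibrous-cap strip (wall between lumen and plaque inner radius, within
    the plaque sector); also reports the von Mises maximum and the maximum
    nodal deformation."""
    mesh = sol.mesh
    princ = sol.principal_stress()
    vm = sol.von_mises()
    centroids = mesh.nodes[mesh.tris].mean(axis=1)
    regions = mesh.regions if mesh.regions is not None else np.zeros(len(mesh.tris), int)
    in_scope = regions == 1
    meta = mesh.metadata
    if "r_plaque_inner" in meta:
        r = np.linalg.norm(centroids, axis=1)
        ang = np.mod(np.arctan2(centroids[:, 1], centroids[:, 0]) - meta["arc_centre"] + np.pi,
                     2 * np.pi) - np.pi
        cap = (
            (regions == 0)
            & (r < meta["r_plaque_inner"])
            & (np.abs(ang) <= meta["arc_extent"] / 2)
        )
        in_scope = in_scope | cap
    if not np.any(in_scope):
        in_scope = np.ones(len(mesh.tris), dtype=bool)
    k = int(np.flatnonzero(in_scope)[np.argmax(princ[in_scope])])
    names = mesh.region_names or {0: "wall"}
    return {
        "pss": float(max(princ[in_scope].max(), 0.0)),
        "pss_location": {
            "region": names[int(regions[k])],
            "x": float(centroids[k, 0]),
            "y": float(centroids[k, 1]),
        },
        "max_von_mises": float(vm[in_scope].max()),
        "max_deformation": sol.max_deformation,
    }
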